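"""Terpene-synthase subfamily and carbocation-mechanism vocabulary.

Class-I plant TPS enzymes ionize a prenyl diphosphate (GPP, FPP, its isomer
NPP, or GGPP) to an initial carbocation; the first committed step — either
deprotonation (acyclic products) or a ring closure (1,6-, 1,10- or
1,11-cyclization for sesquiterpene synthases; terpinyl-cation formation for
cyclic monoterpene synthases) — is conserved within clades and can be
predicted from active-site homology to characterized enzymes. This module
fixes the closed label vocabulary used across the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SUBFAMILIES = ("TPS-a", "TPS-b", "TPS-g", "TPS-c", "TPS-e")

SUBSTRATES = ("GPP", "FPP", "NPP", "GGPP")

CYCLIZATIONS = (
    "acyclic",
    "cyc_1_6",
    "cyc_1_10",
    "cyc_1_11",
    "TypeI_cyclic",
    "TypeII_acyclic",
    "unresolved",
)

_TPS_A_CYC = {"acyclic", "cyc_1_6", "cyc_1_10", "cyc_1_11", "unresolved"}
_TPS_B_CYC = {"TypeI_cyclic", "TypeII_acyclic", "unresolved"}
_TPS_G_SUBSTRATES = ({"GPP"}, {"GPP", "FPP"}, {"GPP", "FPP", "GGPP"})


@dataclass(frozen=True)
class MechanismLabel:
    """Subfamily + initial substrate repertoire + first carbocation step."""

    subfamily: str
    substrates: frozenset = field(default_factory=frozenset)
    cyclization: str = "unresolved"
    product_note: str = ""

    def __post_init__(self):
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if self.cyclization not in CYCLIZATIONS:
            raise ValueError(f"unknown cyclization {self.cyclization!r}")
        unknown = set(self.substrates) - set(SUBSTRATES)
        if unknown:
            raise ValueError(f"unknown substrates {sorted(unknown)}")
        self.validate()

    def validate(self) -> None:
        """Enforce the subfamily-specific label invariants."""
        subs = set(self.substrates)
        if self.subfamily == "TPS-a":
            if not subs or not subs <= {"FPP", "NPP"}:
                raise ValueError("TPS-a labels use FPP and/or NPP substrates")
            if self.cyclization not in _TPS_A_CYC:
                raise ValueError(f"invalid TPS-a cyclization {self.cyclization!r}")
        elif self.subfamily == "TPS-b":
            if "GPP" not in subs or not subs <= {"GPP", "FPP"}:
                raise ValueError("TPS-b labels use GPP (optionally plus FPP)")
            if self.cyclization not in _TPS_B_CYC:
                raise ValueError(f"invalid TPS-b cyclization {self.cyclization!r}")
        elif self.subfamily == "TPS-g":
            if subs not in _TPS_G_SUBSTRATES and self.cyclization != "unresolved":
                raise ValueError("TPS-g labels use one of the three substrate repertoires")

    def key(self) -> tuple:
        """Hashable identity used when checking label recovery."""
        return (self.subfamily, frozenset(self.substrates), self.cyclization)


def _lab(subfamily, substrates, cyclization, note) -> MechanismLabel:
    return MechanismLabel(subfamily, frozenset(substrates), cyclization, note)


#: Mechanism classes per subfamily. TPS-a splits by initial substrate and first
#: cyclization; TPS-b by Type I (cyclic) versus Type II (acyclic) monoterpene
#: mechanisms; TPS-g by substrate repertoire (all products are acyclic terpene
#: alcohols). No TPS-c/e member has a characterized mechanism, so those carry a
#: single unresolved placeholder class.
MECHANISM_CLASSES: dict[str, list[tuple[str, MechanismLabel]]] = {
    "TPS-a": [
        ("a_acyclic_FPP", _lab("TPS-a", ["FPP"], "acyclic",
                               "acyclic sesquiterpenes (farnesene-type)")),
        ("a_16_NPP", _lab("TPS-a", ["NPP"], "cyc_1_6",
                          "1,6-cyclization of the nerolidyl cation (bisabolyl-type)")),
        ("a_110_FPP", _lab("TPS-a", ["FPP"], "cyc_1_10",
                           "1,10-cyclization of the farnesyl cation (germacradienyl-type)")),
        ("a_111_FPP", _lab("TPS-a", ["FPP"], "cyc_1_11",
                           "1,11-cyclization of the farnesyl cation (humulyl-type)")),
    ],
    "TPS-b": [
        ("b_typeI", _lab("TPS-b", ["GPP"], "TypeI_cyclic",
                         "terpinyl cation; cyclic monoterpenes")),
        ("b_typeII", _lab("TPS-b", ["GPP", "FPP"], "TypeII_acyclic",
                          "geranyl/linalyl cation deprotonation; acyclic monoterpenes "
                          "(ocimene/myrcene) and (E,E)-alpha-farnesene from FPP")),
    ],
    "TPS-g": [
        ("g_GPP", _lab("TPS-g", ["GPP"], "acyclic", "geraniol")),
        ("g_dual", _lab("TPS-g", ["GPP", "FPP"], "acyclic",
                        "(3S)-linalool / (E)-nerolidol")),
        ("g_tri", _lab("TPS-g", ["GPP", "FPP", "GGPP"], "acyclic",
                       "(E,E)-geranyl linalool")),
    ],
    "TPS-c": [
        ("c_classII", _lab("TPS-c", ["GGPP"], "unresolved",
                           "ent-copalyl diphosphate synthase-like (class II)")),
    ],
    "TPS-e": [
        ("e_classI", _lab("TPS-e", ["GGPP"], "unresolved",
                          "ent-kaurene synthase-like (class I)")),
    ],
}
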