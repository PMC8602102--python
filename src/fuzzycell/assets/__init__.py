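"""Packaged network assets.

``load_metabolism`` returns the eight-rule AMPK/mTORC1 module exactly as
printed in the source publication.  ``load_tcd4`` returns the 51-node
T CD4 activation network; that file is a synthetic reconstruction (the
original supplementary rule set was not obtainable), see the header of
``tcd4_51_synthetic.rules``.
"""

from __future__ import annotations

from importlib import resources

from ..rules import NetworkModel, parse_rules

__all__ = ["load_metabolism", "load_tcd4", "DISPLAY_NAMES", "NAIVE_INITIAL", "TCD4_BETA"]

#: presentation names for identifiers that cannot be spelled literally
DISPLAY_NAMES = {
    "AMP_ATP": "AMP/ATP",
    "GLYCOLYSIS": "Glycolysis",
    "MHC_A": "MHC/A",
    "PKCTH": "PKCtheta",
    "PLCG": "PLCgamma",
    "IFNGE": "IFNge",
    "IL4E": "IL4e",
    "IL10E": "IL10e",
    "TGFBE": "TGFbe",
    "IL21E": "IL21e",
    "IFNG": "IFNg",
    "TGFB": "TGFb",
    "RORGT": "RORgT",
    "NFKB": "NFkB",
}

#: naive-state initial levels (all other nodes start at 0): basal OXPHOS,
#: high AMP/ATP ratio, active nutrient sensor AMPK
NAIVE_INITIAL = {"OXPHOS": 0.2, "AMP_ATP": 1.0, "AMPK": 1.0}

#: sigmoid gain recorded for the 51-node reconstruction (see asset header)
TCD4_BETA = 10.0


def _read(name: str) -> str:
    return (resources.files(__package__) / name).read_text()


def load_metabolism(beta: float = 5.0, w_thr: float = 0.5) -> NetworkModel:
    """The AMPK/mTORC1 metabolism-control module (8 rules, 5 inputs)."""
    return parse_rules(_read("metabolism.rules"), beta=beta, w_thr=w_thr,
                       display_names=DISPLAY_NAMES)


def load_tcd4(beta: float = TCD4_BETA, w_thr: float = 0.5,
              naive: bool = True) -> NetworkModel:
    """The 51-node T CD4 activation/metabolism network (reconstruction).

    With ``naive=True`` the naive-state initial levels are applied
    (OXPHOS = 0.2, AMP/ATP = 1, AMPK = 1, everything else 0).
    """
    model = parse_rules(_read("tcd4_51_synthetic.rules"), beta=beta,
                        w_thr=w_thr, display_names=DISPLAY_NAMES)
    if naive:
        for name, level in NAIVE_INITIAL.items():
            model.set_initial(name, level)
    return model
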