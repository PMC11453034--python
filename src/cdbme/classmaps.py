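"""Shipped secondary-structure class groupings.

Different SS classification algorithms (DISICL, DSSP, HBSS) and CD-based
estimators (BESTSEL, K2D3, basis-set methods) use different class
vocabularies.  To compare an estimated composition with one computed
from a reference ensemble, the finer scheme is grouped into the coarser
one through a :class:`~cdbme.metrics.ClassMap`.

The maps below cover the comparisons used in the assessment layer:

* DISICL detailed classes -> the 3-class (``DS-dTSC3``) and 6-class
  (``DS5-4SC1``) basis-set schemes;
* DSSP 8-state codes -> the 4-class ``DSSP-1SC3`` scheme;
* HBSS classes -> the 5-class ``HBSS-3SC1`` scheme;
* BESTSEL's eight estimated classes -> six classes (Helix-1/2 merged,
  the three anti-parallel sheet classes kept separate, turn and others
  merged into "Other"), with the counterpart HBSS map onto the same six
  classes (parallel strand subclasses merged, right-/non-/left-twisted
  anti-parallel strands identified with Anti3/Anti2/Anti1);
* the DS-dTSC3 3-class scheme -> K2D3's Alpha/Beta/Coil, where K2D3
  reports only helix and sheet and Coil is completed as
  F_Coil = 1 - (F_Alpha + F_Beta).

The member assignments are configuration data: the groupings follow the
published scheme definitions, but individual memberships can be edited
by constructing a modified ClassMap.
"""

from __future__ import annotations

from .metrics import ClassMap

__all__ = [
    "DISICL_TO_DS_DTSC3",
    "DISICL_TO_DS5_4SC1",
    "DSSP_TO_DSSP_1SC3",
    "HBSS_TO_HBSS_3SC1",
    "BESTSEL_TO_SIX",
    "HBSS_TO_BESTSEL_SIX",
    "DS_DTSC3_TO_K2D3",
    "SHIPPED_MAPS",
]

# DISICL detailed segment classes (helix, strand, turn and irregular
# families) grouped into the three-class basis scheme.
DISICL_TO_DS_DTSC3 = ClassMap(
    source_scheme="DISICL",
    target_scheme="DS-dTSC3",
    target_names=("Alpha", "Beta", "Coil"),
    assignment={
        "ALH": "Alpha",  # alpha helix
        "3TH": "Alpha",  # 3-10 helix
        "PIH": "Alpha",  # pi helix
        "EXT": "Beta",  # extended strand
        "NBS": "Beta",  # normal beta strand
        "HBR": "Beta",  # beta bridge / hairpin
        "TUR": "Coil",
        "PPH": "Coil",  # polyproline-II
        "LHH": "Coil",  # left-handed helix
        "IRR": "Coil",  # irregular
    },
)

DISICL_TO_DS5_4SC1 = ClassMap(
    source_scheme="DISICL",
    target_scheme="DS5-4SC1",
    target_names=("Helix", "Helix3", "Beta", "Turn", "PP2", "Coil"),
    assignment={
        "ALH": "Helix",
        "PIH": "Helix",
        "3TH": "Helix3",
        "EXT": "Beta",
        "NBS": "Beta",
        "HBR": "Beta",
        "TUR": "Turn",
        "PPH": "PP2",
        "LHH": "Coil",
        "IRR": "Coil",
    },
)

# DSSP 8-state codes -> four classes.
DSSP_TO_DSSP_1SC3 = ClassMap(
    source_scheme="DSSP",
    target_scheme="DSSP-1SC3",
    target_names=("Helix", "Beta", "Turn", "Coil"),
    assignment={
        "H": "Helix",
        "G": "Helix",
        "I": "Helix",
        "E": "Beta",
        "B": "Beta",
        "T": "Turn",
        "S": "Turn",
        "C": "Coil",
    },
)

# HBSS hydrogen-bond-based classes -> five classes.
HBSS_TO_HBSS_3SC1 = ClassMap(
    source_scheme="HBSS",
    target_scheme="HBSS-3SC1",
    target_names=("Helix4", "Helix3", "Anti", "Para", "Coil"),
    assignment={
        "Helix4": "Helix4",
        "Helix3": "Helix3",
        "Anti-L": "Anti",
        "Anti-N": "Anti",
        "Anti-R": "Anti",
        "Para-L": "Para",
        "Para-R": "Para",
        "Turn": "Coil",
        "Coil": "Coil",
    },
)

_SIX = ("Helix", "Anti1", "Anti2", "Anti3", "Parallel", "Other")

# BESTSEL's eight estimated classes -> six comparison classes.
BESTSEL_TO_SIX = ClassMap(
    source_scheme="BESTSEL",
    target_scheme="BESTSEL6",
    target_names=_SIX,
    assignment={
        "Helix1": "Helix",
        "Helix2": "Helix",
        "Anti1": "Anti1",
        "Anti2": "Anti2",
        "Anti3": "Anti3",
        "Parallel": "Parallel",
        "Turn": "Other",
        "Others": "Other",
    },
)

# Counterpart HBSS map onto the same six classes: the 4-helix class is
# identified with BESTSEL's merged Helix, the left-handed/non-twisted/
# right-handed anti-parallel strands with Anti1/Anti2/Anti3, all
# parallel strand subclasses are merged, everything else is "Other".
HBSS_TO_BESTSEL_SIX = ClassMap(
    source_scheme="HBSS",
    target_scheme="BESTSEL6",
    target_names=_SIX,
    assignment={
        "Helix4": "Helix",
        "Anti-L": "Anti1",
        "Anti-N": "Anti2",
        "Anti-R": "Anti3",
        "Para-L": "Parallel",
        "Para-R": "Parallel",
        "Helix3": "Other",
        "Turn": "Other",
        "Coil": "Other",
    },
)

# K2D3 reports Alpha and Beta; Coil is completed as the remainder.
DS_DTSC3_TO_K2D3 = ClassMap(
    source_scheme="DS-dTSC3",
    target_scheme="K2D3",
    target_names=("Alpha", "Beta", "Coil"),
    assignment={"Alpha": "Alpha", "Beta": "Beta", "Coil": "Coil"},
    completion="Coil",
)

SHIPPED_MAPS = {
    "disicl_to_ds_dtsc3": DISICL_TO_DS_DTSC3,
    "disicl_to_ds5_4sc1": DISICL_TO_DS5_4SC1,
    "dssp_to_dssp_1sc3": DSSP_TO_DSSP_1SC3,
    "hbss_to_hbss_3sc1": HBSS_TO_HBSS_3SC1,
    "bestsel_to_six": BESTSEL_TO_SIX,
    "hbss_to_bestsel_six": HBSS_TO_BESTSEL_SIX,
    "ds_dtsc3_to_k2d3": DS_DTSC3_TO_K2D3,
}
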