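"""Published descriptive statistics of the I.Family accelerometer subsample.

Mean minutes/day in the traditional intensity categories, by study centre,
as printed in the study's descriptive table. The underlying cohort data are
not publicly available; these printed means serve as fixed reference inputs
for internal-consistency arithmetic — e.g. the MPA:VPA time ratio (children
spend about 15 times longer at moderate than at vigorous intensity), the
corresponding energy-expenditure ratio (vigorous intensity is defined at
twice the energy expenditure of moderate, so the energy ratio is half the
time ratio), and the additivity of MVPA = MPA + VPA + VVPA per centre.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cutpoint_means_min_per_day",
    "mpa_vpa_time_ratio",
    "mpa_vpa_energy_ratio",
    "mvpa_from_components",
]

_CENTRES = ["All", "Italy", "Hungary", "Germany", "Spain", "Sweden", "Poland"]

_MEANS = {
    #           All     Italy   Hungary Germany Spain   Sweden  Poland
    "SED":     [716.7,  742.6,  721.9,  729.7,  703.6,  677.4,  689.1],
    "LPA":     [196.1,  194.9,  194.2,  189.9,  196.3,  193.7,  220.6],
    "MPA":     [98.2,   77.3,   95.1,   92.3,   108.3,  134.1,  102.9],
    "VPA":     [6.55,   4.02,   6.42,   5.87,   8.47,   10.06,  5.83],
    "VVPA":    [2.46,   1.17,   2.34,   2.19,   3.35,   4.72,   1.58],
    "MVPA":    [107.3,  82.5,   103.9,  100.3,  120.1,  148.9,  110.3],
}

#: vigorous intensity starts at 6 METs, moderate at 3 — VPA represents twice
#: the energy expenditure per minute of MPA
_VPA_TO_MPA_ENERGY = 2.0


def cutpoint_means_min_per_day() -> pd.DataFrame:
    """Published mean minutes/day per intensity category and study centre."""
    return pd.DataFrame(_MEANS, index=_CENTRES).T


def mpa_vpa_time_ratio(centre: str = "All") -> float:
    """Ratio of time spent at moderate vs vigorous intensity."""
    t = cutpoint_means_min_per_day()[centre]
    return float(t["MPA"] / t["VPA"])


def mpa_vpa_energy_ratio(centre: str = "All") -> float:
    """Energy-expenditure ratio MPA:VPA (time ratio over the 2× energy cost)."""
    return mpa_vpa_time_ratio(centre) / _VPA_TO_MPA_ENERGY


def mvpa_from_components(centre: str = "Sweden") -> float:
    """MVPA minutes/day recomposed as MPA + VPA + VVPA for a centre."""
    t = cutpoint_means_min_per_day()[centre]
    return float(t["MPA"] + t["VPA"] + t["VVPA"])
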