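"""Per-dendrite excitatory/inhibitory synapse statistics.

Counts per dendrite come from in vivo or histological puncta scoring:
PSD95+ spines and dually innervated spines (DIS, carrying both PSD95 and
gephyrin) are excitatory synapses; shaft gephyrin puncta and the gephyrin
component of DIS are inhibitory. Densities are reported per 100 um of
dendrite; the E/I ratio is their quotient. Whether DIS contribute to the
excitatory count is configurable (inclusive by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "densities",
    "ei_correlation",
    "compare_correlations",
    "fractional_dynamics",
]

REQUIRED_COLUMNS = (
    "length_um",
    "psd95_spines",
    "dual_innervated_spines",
    "shaft_gephyrin",
)


def densities(records: pd.DataFrame, include_dis: bool = True) -> pd.DataFrame:
    """Per-100-um excitatory/inhibitory densities and E/I ratio per dendrite.

    excitatory = (psd95_spines [+ DIS]) / length; inhibitory =
    (shaft_gephyrin + DIS) / length. Dendrites with zero inhibitory synapses
    get a NaN ratio and ``ei_undefined=True``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (records["length_um"] <= 0).any():
        raise ValueError("dendrite lengths must be positive")
    out = records.copy()
    dis = records["dual_innervated_spines"]
    e_counts = records["psd95_spines"] + (dis if include_dis else 0)
    i_counts = records["shaft_gephyrin"] + dis
    out["e_density_per_100um"] = e_counts / records["length_um"] * 100.0
    out["i_density_per_100um"] = i_counts / records["length_um"] * 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(i_counts > 0, e_counts / i_counts, np.nan)
    out["ei_ratio"] = ratio
    out["ei_undefined"] = i_counts == 0
    return out


def ei_correlation(records: pd.DataFrame, include_dis: bool = True
                   ) -> tuple[float, float, int]:
    """Pearson correlation between excitatory and inhibitory synapse density
    across dendrites; returns (r, two-sided p, n)."""
    d = densities(records, include_dis=include_dis)
    e = d["e_density_per_100um"].to_numpy(dtype=float)
    i = d["i_density_per_100um"].to_numpy(dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 dendrites")
    if np.std(e) == 0 or np.std(i) == 0:
        raise ValueError("zero variance in a density; correlation undefined")
    res = stats.pearsonr(e, i)
    return float(res.statistic), float(res.pvalue), int(e.size)


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         sided: str = "two-sided") -> float:
    """Fisher r-to-z comparison of two independent Pearson correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the p value comes
    from the standard normal distribution (``sided`` in two-sided/greater/
    less, referring to r1 - r2).
    """
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must be strictly inside (-1, 1)")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if sided == "two-sided":
        return float(2.0 * stats.norm.sf(abs(z)))
    if sided == "greater":
        return float(stats.norm.sf(z))
    if sided == "less":
        return float(stats.norm.cdf(z))
    raise ValueError(f"unknown sidedness: {sided!r}")


def fractional_dynamics(session1_ids, session2_ids) -> dict:
    """Fractional gain and loss of identity-matched puncta between sessions.

    gain = |S2 \\ S1| / |S2| (new puncta over all puncta in session 2);
    loss = |S1 \\ S2| / |S1|. The gain/loss ratio is NaN when loss is 0.
    """
    s1, s2 = set(session1_ids), set(session2_ids)
    if not s1 or not s2:
        raise ValueError("empty session puncta set; fractions undefined")
    gain = len(s2 - s1) / len(s2)
    loss = len(s1 - s2) / len(s1)
    return {
        "gain": gain,
        "loss": loss,
        "gain_loss_ratio": gain / loss if loss > 0 else float("nan"),
    }
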