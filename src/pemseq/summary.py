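"""Event normalization, group statistics, and vector junction profiles.

Three denominators are used, following the conventions of anchored
editing-outcome sequencing:

* **total events** = indels + large deletions + translocations + uncut
  + AAV integrations (ambiguous molecules excluded everywhere);
* **editing events** for editing efficiency and translocation rates =
  indels + large deletions + translocations, *excluding* AAV
  integrations;
* **editing events for AAV rates** = indels + large deletions +
  translocations + AAV integrations.

These definitions force the identity
``aav_pct_of_total / aav_pct_of_edited = (edited + AAV) / total``,
which is property-tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

from .junctions import JunctionCall
from .simulate import VectorMap


def _pct(num: int, den: int) -> float | None:
    """Percentage to 2 decimals; None for an undefined (0) denominator."""
    if den == 0:
        return None
    return round(100.0 * num / den, 2)


@dataclass(frozen=True)
class EditingSummary:
    """Per-library outcome counts and the three normalized rates."""

    n_indel: int
    n_large_del: int
    n_ot_tx: int
    n_gen_tx: int
    n_aav: int
    n_uncut: int
    n_ambiguous: int
    editing_efficiency: float | None
    ot_tx_pct_of_edited: float | None
    gen_tx_pct_of_edited: float | None
    large_del_pct_of_edited: float | None
    aav_pct_of_total: float | None
    aav_pct_of_edited: float | None

    @property
    def total_events(self) -> int:
        return self.n_indel + self.n_large_del + self.n_ot_tx + self.n_gen_tx + self.n_uncut + self.n_aav

    @property
    def n_edited(self) -> int:
        """Editing events excluding AAV integrations."""
        return self.n_indel + self.n_large_del + self.n_ot_tx + self.n_gen_tx

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total_events"] = self.total_events
        return d


def summarize(calls: list[JunctionCall], count_large_del_as_edited: bool = True) -> EditingSummary:
    """Build an :class:`EditingSummary` from deduplicated molecule calls.

    ``count_large_del_as_edited=False`` drops large deletions from the
    editing-event numerators and denominators (they then still count in
    total events).
    """
    n = {"indel": 0, "large_deletion": 0, "offtarget_translocation": 0,
         "general_translocation": 0, "aav_integration": 0, "uncut": 0, "ambiguous": 0}
    for c in calls:
        n[c.cls] += 1

    n_indel, n_ld = n["indel"], n["large_deletion"]
    n_ot, n_gt = n["offtarget_translocation"], n["general_translocation"]
    n_aav, n_uncut = n["aav_integration"], n["uncut"]

    total = n_indel + n_ld + n_ot + n_gt + n_uncut + n_aav
    edited = n_indel + n_ot + n_gt + (n_ld if count_large_del_as_edited else 0)
    return EditingSummary(
        n_indel=n_indel,
        n_large_del=n_ld,
        n_ot_tx=n_ot,
        n_gen_tx=n_gt,
        n_aav=n_aav,
        n_uncut=n_uncut,
        n_ambiguous=n["ambiguous"],
        editing_efficiency=_pct(edited, total),
        ot_tx_pct_of_edited=_pct(n_ot, edited),
        gen_tx_pct_of_edited=_pct(n_gt, edited),
        large_del_pct_of_edited=_pct(n_ld, edited),
        aav_pct_of_total=_pct(n_aav, total),
        aav_pct_of_edited=_pct(n_aav, edited + n_aav),
    )


def fold_change(a: float, b: float) -> float:
    """Ratio ``a / b`` reported to one decimal.

    ``b`` must be positive: a zero baseline has no defined fold change
    (report a floor with a pseudocount at the caller's discretion).
    """
    if b <= 0:
        raise ValueError("fold change undefined for a non-positive baseline")
    return round(a / b, 1)


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sided t-test with per-group mean and SD."""

    statistic: float
    df: float
    pvalue: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def compare_groups(values_a: list[float], values_b: list[float]) -> GroupComparison:
    """Two-sided unequal-variance (Welch) t-test between two groups.

    Groups need n >= 2.  Degenerate zero-variance groups are handled
    explicitly: equal constant groups give t=0, p=1; separated constant
    groups give p=0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a, sd_b = float(a.std(ddof=1)), float(b.std(ddof=1))
    if sd_a == 0.0 and sd_b == 0.0:
        if mean_a == mean_b:
            return GroupComparison(0.0, float(a.size + b.size - 2), 1.0, mean_a, sd_a, mean_b, sd_b)
        return GroupComparison(math.inf if mean_a > mean_b else -math.inf,
                               float(a.size + b.size - 2), 0.0, mean_a, sd_a, mean_b, sd_b)
    res = sps.ttest_ind(a, b, equal_var=False)
    df = getattr(res, "df", None)
    if df is None:  # pragma: no cover - older scipy without .df
        va, vb = sd_a**2 / a.size, sd_b**2 / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return GroupComparison(float(res.statistic), float(df), float(res.pvalue), mean_a, sd_a, mean_b, sd_b)


@dataclass(frozen=True)
class VectorJunctionProfile:
    """Per-position vector breakpoint histogram and ITR enrichment."""

    histogram: np.ndarray
    itr_fraction: float | None
    n_junctions: int


def vector_junction_profile(calls: list[JunctionCall], vector: VectorMap) -> VectorJunctionProfile:
    """Histogram of AAV-side breakpoints and the fraction inside ITRs.

    Only ``aav_integration`` calls with a vector-side coordinate
    contribute; with zero such calls the histogram is empty and the ITR
    fraction undefined (None).
    """
    n = len(vector.sequence)
    hist = np.zeros(n, dtype=np.int64)
    positions = [
        c.prey_pos for c in calls
        if c.cls == "aav_integration" and 0 <= c.prey_pos < n
    ]
    for p in positions:
        hist[p] += 1
    if not positions:
        return VectorJunctionProfile(hist, None, 0)
    in_itr = sum(vector.in_itr(p) for p in positions)
    return VectorJunctionProfile(hist, in_itr / len(positions), len(positions))
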