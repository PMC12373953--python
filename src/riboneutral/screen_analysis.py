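"""Activity scoring and significance statistics for self-splicing screens.

A screen compares two sequencing samples of the same design pool: a
pre-assay sample (frequencies ``f_ref``) and a post-assay sample in which
only active ribozymes carry the substrate tag S2 at their 3' end
(frequencies ``f_sel``). The per-design activity score is

    act = log10(f_sel / f_ref)

normalized so the reference ribozyme scores 0. Non-functional sequences form
a Gaussian score plateau; its mean and standard deviation define a noise
model from which an activity threshold at a chosen false-positive
probability follows (p = 1e-3 corresponds to z = 3.09). Active fractions per
mutational-distance bin, exact binomial tail tests against the noise null,
and the summary statistics L50 (largest distance holding a >= 50% active
fraction) and Lmax (>= 1%) complete the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import alphabet as ab
from .errors import FitError, InputError

__all__ = [
    "DesignLibrary",
    "ScreenCounts",
    "NoiseModel",
    "ThresholdResult",
    "ScreenSummary",
    "map_reads",
    "activity_scores",
    "fit_noise_model",
    "activity_threshold",
    "active_fraction_curve",
    "binomial_pvalue",
    "estimate_L50_Lmax",
]

#: stringent threshold preset for shallow-sequencing conditions
STRINGENT_THRESHOLD = -1.5


@dataclass
class DesignLibrary:
    """Design id -> sequence, plus the substrate tag expected 3' of active
    designs."""

    designs: dict[str, str]
    s2_tag: str

    def __post_init__(self):
        if not self.designs:
            raise InputError("empty design library")
        self.designs = {k: ab.normalize(v) for k, v in self.designs.items()}
        self.s2_tag = ab.normalize(self.s2_tag)
        if any(ab.GAP in s for s in self.designs.values()):
            raise InputError("designs must be gap-free")


@dataclass
class ScreenCounts:
    """Per-design read counts, pre-assay (count_ref) and substrate-tagged
    post-assay (count_sel)."""

    counts: pd.DataFrame  # index design_id; columns count_ref, count_sel

    def __post_init__(self):
        need = {"count_ref", "count_sel"}
        if not need.issubset(self.counts.columns):
            raise InputError(f"counts table needs columns {sorted(need)}")
        if (self.counts[list(need)] < 0).any().any():
            raise InputError("negative counts")

    @property
    def total_ref(self) -> float:
        return float(self.counts["count_ref"].sum())

    @property
    def total_sel(self) -> float:
        return float(self.counts["count_sel"].sum())


def _norm_read(read: str) -> str:
    return read.upper().replace("T", "U")


def map_reads(
    reads,
    library: DesignLibrary,
    min_cov: float = 0.7,
    tag_len: int = 6,
) -> ScreenCounts:
    """Count reads per design by exact substring matching.

    A read counts for a design when it contains, with full identity, a
    contiguous stretch of the design of length >= ``min_cov`` times the
    design length; reads matching two or more designs are dropped. A read
    additionally counts as substrate-tagged (``count_sel``) when it contains
    the design's 3'-terminal stretch followed immediately by at least
    ``tag_len`` bases of S2.
    """
    items = list(library.designs.items())
    tag = library.s2_tag[:tag_len]
    ids = [k for k, _ in items]
    kmin = {k: max(1, math.ceil(min_cov * len(s))) for k, s in items}
    n_ref = dict.fromkeys(ids, 0)
    n_sel = dict.fromkeys(ids, 0)
    for read in reads:
        r = _norm_read(str(getattr(read, "seq", read)))
        hits = []
        for k, s in items:
            kk = kmin[k]
            if any(s[i : i + kk] in r for i in range(len(s) - kk + 1)):
                hits.append(k)
                if len(hits) > 1:
                    break
        if len(hits) != 1:
            continue
        k = hits[0]
        n_ref[k] += 1
        if library.designs[k][-kmin[k]:] + tag in r:
            n_sel[k] += 1
    df = pd.DataFrame({"count_ref": n_ref, "count_sel": n_sel})
    df.index.name = "design_id"
    return ScreenCounts(counts=df)


def activity_scores(
    counts: ScreenCounts,
    ref_id: str,
    distances: dict[str, int] | pd.Series | None = None,
    min_ref: float = 5,
) -> pd.DataFrame:
    """Per-design activity table.

    ``act = log10(f_sel / f_ref)`` shifted so the reference design scores 0.
    Designs with ``count_ref`` below ``min_ref`` are flagged ``excluded``
    (they leave all denominators); detected designs with ``count_sel = 0``
    are flagged ``inactive`` (below any threshold, act undefined).
    """
    df = counts.counts.copy()
    tot_ref, tot_sel = counts.total_ref, counts.total_sel
    if tot_ref <= 0 or tot_sel <= 0:
        raise InputError("zero total counts")
    if ref_id not in df.index:
        raise InputError(f"reference design {ref_id!r} absent from counts")
    df["f_ref"] = df["count_ref"] / tot_ref
    df["f_sel"] = df["count_sel"] / tot_sel
    df["excluded"] = df["count_ref"] < min_ref
    df["inactive"] = (~df["excluded"]) & (df["count_sel"] <= 0)
    ok = (~df["excluded"]) & (~df["inactive"])
    with np.errstate(divide="ignore"):
        raw = np.where(ok, np.log10(df["f_sel"] / df["f_ref"]), np.nan)
    if df.loc[ref_id, "excluded"] or df.loc[ref_id, "inactive"]:
        raise InputError("reference design has no usable score for normalization")
    ref_act = raw[df.index.get_loc(ref_id)]
    df["act"] = raw - ref_act
    if distances is not None:
        df["distance"] = pd.Series(dict(distances)).reindex(df.index)
    return df


@dataclass
class NoiseModel:
    """Gaussian model of the non-functional score plateau."""

    mu: float
    sigma: float
    n_fit: int
    n_inactive: int = 0
    normality_p: float = float("nan")

    def threshold(self, z: float) -> float:
        return self.mu + z * self.sigma

    def pi(self, z: float) -> float:
        """Upper-tail probability that a noise score exceeds mu + z sigma."""
        return float(sps.norm.sf(z))


def fit_noise_model(
    table: pd.DataFrame, min_distance: int = 100, min_n: int = 30
) -> NoiseModel:
    """Fit the noise Gaussian on scores of designs at >= ``min_distance``
    mutations (far enough that none is functional). Inactive-flagged designs
    carry no score; they are excluded from the fit and reported in
    ``n_inactive``."""
    if "distance" not in table.columns:
        raise InputError("activity table lacks distances")
    far = table[table["distance"] >= min_distance]
    scores = far.loc[~far["excluded"] & ~far["inactive"], "act"].to_numpy()
    if scores.size < min_n:
        raise FitError(f"only {scores.size} usable noise scores (need {min_n})")
    sigma = float(scores.std(ddof=1))
    if sigma <= 0:
        raise FitError("degenerate noise sample: zero variance")
    normality_p = float(sps.normaltest(scores).pvalue) if scores.size >= 20 else float("nan")
    return NoiseModel(
        mu=float(scores.mean()), sigma=sigma, n_fit=int(scores.size),
        n_inactive=int(far["inactive"].sum()), normality_p=normality_p,
    )


@dataclass
class ThresholdResult:
    threshold: float
    z: float
    p_target: float


def activity_threshold(noise: NoiseModel, p_target: float = 1e-3) -> ThresholdResult:
    """Activity threshold at upper-tail probability ``p_target`` of the noise
    Gaussian: ``z = Phi^{-1}(1 - p)``, threshold ``mu + z sigma``."""
    if not (0 < p_target < 0.5):
        raise InputError("p_target must lie in (0, 0.5)")
    z = float(sps.norm.isf(p_target))
    return ThresholdResult(threshold=noise.threshold(z), z=z, p_target=p_target)


def binomial_pvalue(N: int, n: int, pi: float) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= n | N, pi),
    summed in exact rational arithmetic (no normal approximation)."""
    if not (0 <= n <= N):
        raise InputError("need 0 <= n <= N")
    if not (0 < pi < 1):
        raise InputError("pi must lie in (0, 1)")
    if n == 0:
        return 1.0
    p = Fraction(pi)
    q = 1 - p
    if n <= N // 2:
        # complement of the lower tail, exactly
        s = sum(
            Fraction(math.comb(N, i)) * p**i * q ** (N - i) for i in range(n)
        )
        return float(1 - s)
    s = sum(Fraction(math.comb(N, i)) * p**i * q ** (N - i) for i in range(n, N + 1))
    return float(s)


def active_fraction_curve(
    table: pd.DataFrame,
    threshold: float,
    bin_width: int = 5,
    err_band: float = 0.3,
    pi: float = 1e-3,
) -> pd.DataFrame:
    """Active fraction per half-open distance bin (a, a+width].

    Excluded designs leave the denominator; inactive designs count as below
    threshold. The error band counts scores within +-``err_band`` of the
    threshold as active (upper bound) or inactive (lower bound). Each bin
    carries the exact binomial p-value of its active count against the noise
    null probability ``pi``. The reference (distance 0) is not binned.
    """
    if "distance" not in table.columns:
        raise InputError("activity table lacks distances")
    t = table[(~table["excluded"]) & (table["distance"] > 0)].copy()
    act = t["act"].to_numpy()
    inactive = t["inactive"].to_numpy()

    def above(cut):
        return (~inactive) & (act >= cut)

    dmax = int(t["distance"].max()) if len(t) else 0
    rows = []
    for lo in range(0, dmax, bin_width):
        hi = lo + bin_width
        sel = (t["distance"] > lo) & (t["distance"] <= hi)
        N = int(sel.sum())
        n = int((above(threshold) & sel).sum())
        n_up = int((above(threshold - err_band) & sel).sum())
        n_lo = int((above(threshold + err_band) & sel).sum())
        rows.append({
            "lo": lo, "hi": hi, "N": N, "n": n,
            "fraction": n / N if N else float("nan"),
            "upper": n_up / N if N else float("nan"),
            "lower": n_lo / N if N else float("nan"),
            "pvalue": binomial_pvalue(N, n, pi) if N else float("nan"),
        })
    return pd.DataFrame(rows)


@dataclass
class ScreenSummary:
    """Largest distances holding 50% / 1% active fractions with binomial
    significance, per the noise-null test."""

    L50: int | None
    Lmax: int | None
    active_fraction_at_Lmax: float | None = None

    def __post_init__(self):
        if self.L50 is not None and self.Lmax is not None and self.L50 > self.Lmax:
            raise InputError("L50 cannot exceed Lmax")


def estimate_L50_Lmax(
    bins: pd.DataFrame, pi: float = 1e-3, alpha: float = 1e-3
) -> ScreenSummary:
    """L50 = largest bin upper edge with active fraction >= 0.5 and exact
    binomial p < ``alpha`` against null probability ``pi``; Lmax likewise at
    fraction >= 0.01."""
    L50 = Lmax = None
    af_at_lmax = None
    for _, row in bins.iterrows():
        if not row["N"]:
            continue
        p = row["pvalue"] if np.isfinite(row["pvalue"]) else binomial_pvalue(
            int(row["N"]), int(row["n"]), pi)
        if p < alpha and row["fraction"] >= 0.5:
            L50 = int(row["hi"])
        if p < alpha and row["fraction"] >= 0.01:
            Lmax = int(row["hi"])
            af_at_lmax = float(row["fraction"])
    return ScreenSummary(L50=L50, Lmax=Lmax, active_fraction_at_Lmax=af_at_lmax)
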