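"""T-RFLP community profiles and permutation statistics.

Processing follows standard community-fingerprint practice: terminal
restriction fragments (T-RFs) shorter than 50 bp are discarded as primer-dimer
noise, fragment lengths are binned at 2 bp, rare bins (present in no more than
2 % of samples) are dropped, and peak heights are relativized within samples.

Downstream statistics are Bray-Curtis dissimilarity, a permutation Mantel test
and a one-way-per-term PERMANOVA on the distance matrix, plus plain Pearson
correlations for rate-vs-rate and abundance-vs-rate relations.  These are
implemented here directly (they are small and auditable); scikit-bio serves as
an independent cross-check in the test suite only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeakTable",
    "CommunityMatrix",
    "process_peaks",
    "bin_fragments",
    "bray_curtis",
    "bray_curtis_matrix",
    "mantel",
    "permanova",
    "correlate_rates",
    "pcoa_coordinates",
]


class CommunityError(ValueError):
    """Invalid community-analysis input."""


@dataclass
class PeakTable:
    """One sample's electropherogram peaks: (fragment bp, fluorescence height)."""

    sample_id: str
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for frag, height in self.peaks:
            if frag <= 0:
                raise CommunityError("fragment length must be positive")
            if height < 0:
                raise CommunityError("peak height must be non-negative")


@dataclass
class CommunityMatrix:
    """Samples x binned-T-RF relative abundances with metadata."""

    abundances: pd.DataFrame               # rows = samples, cols = "TRF_<len>"
    bin_registry: dict[str, float] = field(default_factory=dict)
    metadata: pd.DataFrame | None = None
    excluded_samples: list[str] = field(default_factory=list)


def bin_fragments(lengths: list[float], bin_width: float = 2.0) -> dict[float, float]:
    """Single-pass, seeded binning of fragment lengths.

    Lengths are scanned in ascending order; a bin is seeded at the smallest
    unassigned length and collects every fragment in the closed-open window
    [seed, seed + bin_width).  Returns fragment -> bin representative (seed).
    Deterministic and order-stable.
    """
    if bin_width <= 0:
        raise CommunityError("bin width must be positive")
    assignment: dict[float, float] = {}
    seed = None
    for frag in sorted(set(lengths)):
        if seed is None or frag >= seed + bin_width:
            seed = frag
        assignment[frag] = seed
    return assignment


def process_peaks(
    tables: list[PeakTable],
    min_len: float = 50.0,
    bin_width: float = 2.0,
    occurrence: float = 0.02,
    min_height: float = 0.0,
    metadata: pd.DataFrame | None = None,
) -> CommunityMatrix:
    """Peak tables -> relativized community matrix.

    Steps, in order: drop peaks below ``min_height`` (noise filter, off by
    default) and shorter than ``min_len`` bp (boundary closed: 50.0 bp is
    kept); bin fragment lengths at ``bin_width``; sum heights within bins per
    sample; drop bins present (height > 0) in <= ``occurrence`` fraction of
    samples (strict inequality required to keep); relativize rows to sum 1.
    Samples with zero total height after filtering are excluded with a
    warning.
    """
    if not tables:
        raise CommunityError("no samples supplied")
    if min_len <= 0 or bin_width <= 0 or not 0 <= occurrence < 1:
        raise CommunityError("thresholds out of range")
    kept = [
        (t.sample_id, frag, h)
        for t in tables
        for frag, h in t.peaks
        if frag >= min_len and h >= min_height and h > 0
    ]
    if not kept:
        raise CommunityError("no peaks retained after filtering")
    frame = pd.DataFrame(kept, columns=["sample_id", "fragment", "height"])
    assignment = bin_fragments(frame["fragment"].tolist(), bin_width)
    frame["bin"] = frame["fragment"].map(assignment)
    wide = (
        frame.pivot_table(index="sample_id", columns="bin", values="height",
                          aggfunc="sum", fill_value=0.0)
        .reindex([t.sample_id for t in tables], fill_value=0.0)
    )
    n_samples = len(tables)
    presence = (wide > 0).sum(axis=0)
    keep_bins = presence[presence > occurrence * n_samples].index
    wide = wide[keep_bins]

    totals = wide.sum(axis=1)
    excluded = totals.index[totals <= 0].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) with zero total height excluded: {excluded[:5]}",
            stacklevel=2,
        )
        wide = wide.loc[totals > 0]
        totals = totals[totals > 0]
    rel = wide.div(totals, axis=0)
    rel.columns = [f"TRF_{b:g}" for b in rel.columns]
    registry = {f"TRF_{b:g}": float(b) for b in keep_bins}
    meta = None
    if metadata is not None:
        meta = metadata.set_index("sample_id").loc[rel.index].reset_index() \
            if "sample_id" in metadata.columns else metadata.loc[rel.index]
    return CommunityMatrix(rel, registry, meta, excluded)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CommunityError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise CommunityError("abundances must be non-negative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise CommunityError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(abundances: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Bray-Curtis matrix over rows of an abundance table."""
    vals = abundances.to_numpy(dtype=float)
    n = len(vals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(d, index=abundances.index, columns=abundances.index)


def _as_square(d) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise CommunityError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise CommunityError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
        raise CommunityError("distance matrix must have zero diagonal")
    return arr


def mantel(
    d1, d2,
    permutations: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Permutation Mantel test between two distance matrices.

    r is the Pearson correlation of the lower-triangle vectors; the p-value
    permutes the rows/columns of ``d2`` jointly and is one-sided greater by
    default: p = (1 + #{r_perm >= r_obs}) / (permutations + 1).
    """
    a = _as_square(d1)
    b = _as_square(d2)
    if a.shape != b.shape:
        raise CommunityError("distance matrices must match in size")
    if permutations < 99:
        raise CommunityError("use at least 99 permutations")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    va = a[il]
    if np.std(va) == 0 or np.std(b[il]) == 0:
        raise CommunityError("constant distance vector: Mantel r undefined")

    def corr(mat_b_perm):
        return float(np.corrcoef(va, mat_b_perm[il])[0, 1])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r_perm = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_perm >= r_obs
        elif alternative == "two-sided":
            count += abs(r_perm) >= abs(r_obs)
        else:
            raise CommunityError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (permutations + 1)
    return r_obs, float(p)


def _permanova_ss(d2_sq: np.ndarray, groups: np.ndarray) -> tuple[float, float, int]:
    """(SS_among, SS_within, n_groups) from squared distances and labels."""
    n = d2_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2_sq[iu].sum()) / n
    ss_within = 0.0
    labels = np.unique(groups)
    for g in labels:
        mask = groups == g
        ng = int(mask.sum())
        sub = d2_sq[np.ix_(mask, mask)]
        ss_within += float(sub[np.triu_indices(ng, k=1)].sum()) / ng
    return ss_total - ss_within, ss_within, len(labels)


def permanova(
    d,
    factors: pd.DataFrame,
    permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a distance matrix.

    Each column of ``factors`` is tested as a one-way term: the total sum of
    squared distances (sum d_ij^2 / n) is split into among- and within-group
    components, pseudo-F = (SS_among/df_among) / (SS_within/df_within), and
    the p-value comes from free permutation of sample labels.  Terms are
    tested independently (sequential partitioning of crossed designs is out of
    scope of this implementation and noted in the docs).
    """
    arr = _as_square(d)
    n = arr.shape[0]
    if len(factors) != n:
        raise CommunityError("factor table length must match distance matrix")
    if permutations < 99:
        raise CommunityError("use at least 99 permutations")
    d_sq = arr**2
    rng = np.random.default_rng(seed)
    rows = []
    for term in factors.columns:
        groups = factors[term].to_numpy()
        labels, counts = np.unique(groups, return_counts=True)
        if len(labels) < 2:
            raise CommunityError(f"term {term!r} has fewer than 2 groups")
        if np.any(counts < 2):
            raise CommunityError(f"term {term!r} has a single-sample group (0 within-df)")
        ss_a, ss_w, a = _permanova_ss(d_sq, groups)
        df_a, df_w = a - 1, n - a
        f_obs = (ss_a / df_a) / (ss_w / df_w)
        count = 0
        for _ in range(permutations):
            gp = groups[rng.permutation(n)]
            ss_a_p, ss_w_p, _ = _permanova_ss(d_sq, gp)
            f_p = (ss_a_p / df_a) / (ss_w_p / df_w)
            count += f_p >= f_obs
        rows.append({
            "term": term, "df": df_a, "df_resid": df_w,
            "ss_among": ss_a, "ss_within": ss_w,
            "pseudo_F": float(f_obs), "p": (1 + count) / (permutations + 1),
            "permutations": permutations, "seed": seed,
        })
    return pd.DataFrame(rows)


def correlate_rates(x, y, alpha: float = 0.05) -> dict[str, float]:
    """Pearson correlation with two-sided p and an OLS fit with CIs.

    Used for rate-vs-rate and gene-abundance-vs-rate relations across
    treatment cells.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise CommunityError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CommunityError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(1 - alpha / 2, len(x) - 2)
    return {
        "r": float(r), "p": float(p),
        "slope": float(fit.slope), "intercept": float(fit.intercept),
        "slope_ci_lo": float(fit.slope - tcrit * fit.stderr),
        "slope_ci_hi": float(fit.slope + tcrit * fit.stderr),
        "n": int(len(x)),
    }


def pcoa_coordinates(d, n_axes: int = 2) -> pd.DataFrame:
    """Principal-coordinates projection of a distance matrix (plotting aid).

    Classical metric MDS via double-centering; negative eigenvalues (possible
    for semi-metric Bray-Curtis) are dropped.
    """
    arr = _as_square(d)
    n = arr.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (arr**2) @ j
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10
    coords = v[:, pos] * np.sqrt(w[pos])
    k = min(n_axes, coords.shape[1])
    idx = d.index if isinstance(d, pd.DataFrame) else range(n)
    return pd.DataFrame(coords[:, :k], index=idx,
                        columns=[f"PCo{i+1}" for i in range(k)])
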