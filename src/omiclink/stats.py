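"""Phenotype typing, differential-expression tests, BH-FDR, enrichment.

Test selection follows the phenotype kind and the chosen family:

============  ============================  =========================
phenotype     parametric                    nonparametric
============  ============================  =========================
binary        Welch two-sample t            Mann-Whitney U (two-sided)
categorical   one-way ANOVA                 Kruskal-Wallis
continuous    least-squares slope t         (not defined)
============  ============================  =========================

The Mann-Whitney test uses the exact null distribution for combined
n <= 20 without ties, and the tie-corrected normal approximation otherwise.
Kruskal-Wallis uses exhaustive permutation enumeration for total n <= 12
and the chi-square approximation above that.

Benjamini-Hochberg adjustment is always computed over exactly the supplied
p-value vector: the multiple-testing background is the set of molecules the
user selected for display, not the whole dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .errors import ValidationError
from .io_model import OmicsLayer, is_missing_token

# ---------------------------------------------------------------------------
# phenotype typing


@dataclass
class PhenotypeDescriptor:
    name: str
    kind: str                      # "binary" | "categorical" | "continuous"
    levels: list = field(default_factory=list)
    values: np.ndarray = None      # per-sample vector, aligned by the caller

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValidationError(f"phenotype kind {self.kind!r} invalid")
        if self.kind == "binary" and len(self.levels) != 2:
            raise ValidationError(f"binary phenotype {self.name!r} must have exactly 2 levels")
        if self.kind == "categorical" and len(self.levels) < 3:
            raise ValidationError(f"categorical phenotype {self.name!r} must have >=3 levels")


def _as_float(v) -> float | None:
    if v is None:
        return None
    if isinstance(v, (int, float, np.integer, np.floating)):
        f = float(v)
        return None if math.isnan(f) else f
    s = str(v).strip()
    if is_missing_token(s):
        return None
    try:
        return float(s)
    except ValueError:
        return None


def classify_phenotype(values, name: str = "", kind: str | None = None) -> PhenotypeDescriptor:
    """Automatically type a phenotype as binary, categorical or continuous.

    Two distinct values -> binary. More than two: numeric vectors with few
    distinct values (<= max(5, 10% of n)) are treated as encoded categories,
    otherwise continuous; non-numeric vectors are categorical. ``kind``
    overrides the heuristic.
    """
    vals = list(values)
    if len(vals) < 2:
        raise ValidationError(f"phenotype {name!r}: need at least 2 samples")
    non_missing = [v for v in vals if not is_missing_token(str(v))]
    distinct: list = []
    for v in non_missing:
        if v not in distinct:
            distinct.append(v)
    if len(distinct) < 2:
        raise ValidationError(f"phenotype {name!r}: all values identical, nothing to test")
    numeric = [_as_float(v) for v in non_missing]
    all_numeric = all(f is not None for f in numeric)
    if kind is None:
        if len(distinct) == 2:
            kind = "binary"
        elif all_numeric:
            threshold = max(5, 0.10 * len(vals))
            kind = "categorical" if len(distinct) <= threshold else "continuous"
        else:
            kind = "categorical"
    if kind == "continuous":
        if not all_numeric:
            raise ValidationError(f"phenotype {name!r}: continuous phenotype must be numeric")
        arr = np.array([_as_float(v) if not is_missing_token(str(v)) else np.nan for v in vals], dtype=float)
        return PhenotypeDescriptor(name=name, kind="continuous", levels=[], values=arr)
    return PhenotypeDescriptor(
        name=name, kind=kind, levels=distinct, values=np.array(vals, dtype=object)
    )


# ---------------------------------------------------------------------------
# differential expression


@dataclass
class TestResult:
    feature_row: int
    statistic: float
    p_value: float
    test_name: str
    q_value: float = math.nan
    flag: str | None = None        # "insufficient_data" | "zero_variance" | "degenerate_separation"

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


MWU_EXACT_MAX_N = 20      # combined sample size for the exact Mann-Whitney path
KW_EXACT_MAX_N = 12       # total sample size for exhaustive Kruskal-Wallis enumeration


def mannwhitney_p(x: np.ndarray, y: np.ndarray) -> tuple:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else asymptotic."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not ties and len(x) + len(y) <= MWU_EXACT_MAX_N:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _kw_statistic(rank_sums: np.ndarray, sizes: np.ndarray, n: int, tie_term: float) -> np.ndarray:
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes, axis=-1) - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else h


def kruskal_exact_p(groups: list) -> tuple:
    """Exhaustive-permutation Kruskal-Wallis: P(H >= h_obs) over all label assignments."""
    data = np.concatenate(groups)
    n = len(data)
    sizes = np.array([len(g) for g in groups])
    ranks = sps.rankdata(data)
    _, counts = np.unique(data, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    obs_sums = []
    pos = 0
    for g in groups:
        obs_sums.append(ranks[pos : pos + len(g)].sum())
        pos += len(g)
    h_obs = float(_kw_statistic(np.array(obs_sums), sizes, n, tie_term))

    # enumerate every split of the rank multiset into groups of the given sizes
    count_ge = 0
    total = 0

    def rec(remaining: tuple, gi: int, sums: list) -> None:
        nonlocal count_ge, total
        if gi == len(sizes) - 1:
            s = sums + [sum(remaining)]
            h = float(_kw_statistic(np.array(s), sizes, n, tie_term))
            total += 1
            if h >= h_obs - 1e-12:
                count_ge += 1
            return
        for combo in itertools.combinations(range(len(remaining)), int(sizes[gi])):
            chosen = sum(remaining[c] for c in combo)
            rest = tuple(r for k, r in enumerate(remaining) if k not in combo)
            rec(rest, gi + 1, sums + [chosen])

    rec(tuple(ranks), 0, [])
    return h_obs, count_ge / total


def kruskal_p(groups: list) -> tuple:
    n = sum(len(g) for g in groups)
    if n <= KW_EXACT_MAX_N:
        return kruskal_exact_p(groups)
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _level_masks(pheno: PhenotypeDescriptor) -> list:
    return [np.array([p == level for p in pheno.values]) for level in pheno.levels]


def _group_split(values: np.ndarray, masks: list) -> list:
    """Per-level non-missing value arrays for one feature."""
    groups = []
    for mask in masks:
        g = values[mask]
        groups.append(g[~np.isnan(g)])
    return groups


def _test_one(values: np.ndarray, pheno: PhenotypeDescriptor, family: str, row: int,
              masks: list | None = None) -> TestResult:
    if pheno.kind == "continuous":
        x = pheno.values.astype(float)
        ok = ~np.isnan(values) & ~np.isnan(x)
        name = "ls-regression"
        if ok.sum() < 3 or len(np.unique(x[ok])) < 2:
            return TestResult(row, math.nan, math.nan, name, flag="insufficient_data")
        if np.ptp(values[ok]) == 0.0:
            return TestResult(row, 0.0, 1.0, name, flag="zero_variance")
        fit = sps.linregress(x[ok], values[ok])
        return TestResult(row, float(fit.slope / fit.stderr) if fit.stderr > 0 else 0.0,
                          float(fit.pvalue), name)

    groups = _group_split(values, masks if masks is not None else _level_masks(pheno))
    name = {
        ("binary", "parametric"): "welch-t",
        ("binary", "nonparametric"): "mann-whitney-u",
        ("categorical", "parametric"): "anova",
        ("categorical", "nonparametric"): "kruskal-wallis",
    }[(pheno.kind, family)]
    if any(len(g) < 2 for g in groups):
        return TestResult(row, math.nan, math.nan, name, flag="insufficient_data")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0.0:
        return TestResult(row, 0.0, 1.0, name, flag="zero_variance")
    if all(np.ptp(g) == 0.0 for g in groups):
        # perfect separation: groups internally constant at distinct values
        return TestResult(row, math.inf, 0.0, name, flag="degenerate_separation")
    if name == "welch-t":
        res = sps.ttest_ind(groups[0], groups[1], equal_var=False)
        return TestResult(row, float(res.statistic), float(res.pvalue), name)
    if name == "mann-whitney-u":
        stat, p = mannwhitney_p(groups[0], groups[1])
        return TestResult(row, stat, p, name)
    if name == "anova":
        res = sps.f_oneway(*groups)
        return TestResult(row, float(res.statistic), float(res.pvalue), name)
    stat, p = kruskal_p(groups)
    return TestResult(row, stat, p, name)


def de_test(
    layer: OmicsLayer,
    pheno: PhenotypeDescriptor,
    family: str = "parametric",
    rows: list | None = None,
) -> list:
    """Differential-expression test of every (selected) feature against a phenotype.

    ``pheno.values`` must be aligned to ``layer.sample_columns``. Missing
    measurements are dropped per feature; features leaving a group with
    fewer than 2 values are flagged ``insufficient_data`` (p = NaN) and are
    excluded from BH and from filtering.
    """
    if family not in ("parametric", "nonparametric"):
        raise ValidationError(f"family must be parametric/nonparametric, got {family!r}")
    if pheno.kind == "continuous" and family == "nonparametric":
        raise ValidationError(
            "no nonparametric test is defined for continuous phenotypes; "
            "use family='parametric' (least-squares regression)"
        )
    if len(pheno.values) != len(layer.sample_columns):
        raise ValidationError(
            f"phenotype {pheno.name!r} has {len(pheno.values)} values but layer "
            f"{layer.name!r} has {len(layer.sample_columns)} sample columns"
        )
    mat = layer.matrix()
    # samples with a missing phenotype value never enter any test
    if pheno.kind == "continuous":
        keep = ~np.isnan(pheno.values.astype(float))
    else:
        keep = np.array([not is_missing_token(str(v)) for v in pheno.values])
    mat = mat[:, keep]
    pheno = replace(pheno, values=pheno.values[keep])
    masks = None if pheno.kind == "continuous" else _level_masks(pheno)
    target_rows = list(range(layer.n_features)) if rows is None else list(rows)
    return [_test_one(mat[r], pheno, family, r, masks) for r in target_rows]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; invariant under
    permutation of the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1] with no NaN")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def attach_q(results: list) -> list:
    """Fill q_value on every testable result, BH over exactly this batch."""
    testable = [r for r in results if not math.isnan(r.p_value)]
    if testable:
        q = bh_adjust([r.p_value for r in testable])
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
    return results


def filter_by_significance(results: list, alpha_p: float, alpha_fdr: float | None = None) -> list:
    """Feature rows passing p <= alpha_p and (optionally) BH q <= alpha_fdr.

    BH is computed on the supplied result set only — the selected-molecule
    background. Flagged/untestable features are never retained.
    """
    for a in (alpha_p,) + ((alpha_fdr,) if alpha_fdr is not None else ()):
        if not (0.0 <= a <= 1.0):
            raise ValidationError(f"threshold {a} outside [0, 1]")
    attach_q(results)
    kept = []
    for r in results:
        if math.isnan(r.p_value):
            continue
        if r.p_value <= alpha_p and (alpha_fdr is None or r.q_value <= alpha_fdr):
            kept.append(r.feature_row)
    return kept


# ---------------------------------------------------------------------------
# hypergeometric enrichment


@dataclass
class EnrichmentResult:
    group_id: str
    display_name: str
    overlap_count: int     # k: DE members of the group in the background
    group_size: int        # K: group members in the background
    de_count: int          # n: DE molecules
    background_size: int   # N
    p_value: float
    q_value: float = math.nan


def enrichment_test(de_features: set, group_anchors: set, background: set,
                    group_id: str = "", display_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= k) for one functional group.

    The background is the set of molecules present in the selected omics
    dataset; ``de_features`` must be a subset of it.
    """
    if not background:
        raise ValidationError("enrichment background must be nonempty")
    if not set(de_features) <= set(background):
        raise ValidationError("de_features must be a subset of the background")
    N = len(background)
    K = len(group_anchors & background)
    n = len(de_features)
    k = len(de_features & group_anchors & background)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(group_id, display_name, k, K, n, N, min(p, 1.0))


def enrich(kb, de_anchors: set, background: set,
           min_group_size: int = 1, min_de_members: int = 1) -> list:
    """Enrichment of every KB gene set, ascending p, BH-adjusted.

    Size filters (minimum group size in background, minimum DE members)
    apply before adjustment, mirroring a report the user can act on.
    """
    results = []
    for g in kb.gene_sets:
        res = enrichment_test(de_anchors, kb.group_anchors(g), background,
                              group_id=g.group_id, display_name=g.display_name)
        if res.group_size >= min_group_size and res.overlap_count >= min_de_members:
            results.append(res)
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.group_id))
    return results


def write_enrichment_report(results: list, path: str) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group_id", "name", "k", "K", "n", "N", "p_value", "q_value"])
        for r in results:
            w.writerow([r.group_id, r.display_name, r.overlap_count, r.group_size,
                        r.de_count, r.background_size, repr(r.p_value), repr(r.q_value)])
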