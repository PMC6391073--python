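"""Label-free proteomics statistics: filtering, growth-dependence calls,
profile clustering and GO-slim enrichment.

The pipeline mirrors standard post-processing of MaxQuant proteinGroups
output: contaminant/reverse and low-evidence proteins are removed, a
missing-value rule keeps proteins with at least one complete condition
group, growth dependence is called per protein by pairwise Kruskal-Wallis
tests across condition groups (dependent if any pair differs at alpha,
deliberately without multiplicity correction), dependent proteins are
clustered on mean-normalized median profiles by k-means with the elbow
rule, and functional imbalance between dependent and independent proteins
is assessed per GO-slim category with two-sided Fisher exact tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

DEFAULT_TRIVIAL_CATEGORIES = frozenset({"unknown", "putative"})


@dataclass
class IntensityMatrix:
    """Proteins x samples quantification table with metadata.

    ``lfq`` and ``ibaq`` are DataFrames indexed by protein accession with
    one column per sample; missing values are NaN (zero intensities should
    be converted to NaN by the reader).  ``groups`` maps each sample
    (column) to its condition label.
    """

    lfq: pd.DataFrame
    ibaq: pd.DataFrame
    peptide_counts: pd.Series
    contaminant: pd.Series
    reverse: pd.Series
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        idx = self.lfq.index
        if idx.has_duplicates:
            raise ValueError("duplicated protein accessions")
        for name in ("ibaq",):
            other = getattr(self, name)
            if not other.index.equals(idx) or \
                    list(other.columns) != list(self.lfq.columns):
                raise ValueError(f"{name} layer is not aligned with lfq")
        for name in ("peptide_counts", "contaminant", "reverse"):
            if not getattr(self, name).index.equals(idx):
                raise ValueError(f"{name} is not aligned with the protein index")
        missing = set(self.lfq.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if (self.lfq.fillna(0) < 0).any().any():
            raise ValueError("intensities must be >= 0")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.lfq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def group_names(self) -> list[str]:
        seen = dict.fromkeys(self.groups[s] for s in self.samples)
        return list(seen)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def subset(self, ids: Sequence[str]) -> "IntensityMatrix":
        ids = list(ids)
        return IntensityMatrix(
            lfq=self.lfq.loc[ids], ibaq=self.ibaq.loc[ids],
            peptide_counts=self.peptide_counts.loc[ids],
            contaminant=self.contaminant.loc[ids],
            reverse=self.reverse.loc[ids], groups=dict(self.groups))

    def __len__(self) -> int:
        return len(self.lfq)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_protein_groups(matrix: IntensityMatrix, min_peptides: int = 2,
                          missing_rule: str = "keep_complete_group",
                          ) -> tuple[IntensityMatrix, dict[str, int]]:
    """Apply the identification-quality and missing-value filters.

    Removes contaminant and reverse (decoy) entries and proteins
    identified with fewer than ``min_peptides`` peptides; then applies the
    missing-value rule on the LFQ layer:

    * ``"keep_complete_group"`` (default): retain proteins that have at
      least one condition group with no missing values;
    * ``"drop_complete_group"``: the opposite (grammatically possible)
      reading -- drop such proteins.

    Returns the filtered matrix and per-rule removal counts.
    """
    if missing_rule not in ("keep_complete_group", "drop_complete_group"):
        raise ValueError(f"unknown missing_rule {missing_rule!r}")
    flagged = matrix.contaminant | matrix.reverse
    low_evidence = ~flagged & (matrix.peptide_counts < min_peptides)
    keep0 = ~(flagged | low_evidence)
    has_complete = pd.Series(False, index=matrix.lfq.index)
    for g in matrix.group_names:
        cols = matrix.group_columns(g)
        has_complete |= matrix.lfq[cols].notna().all(axis=1)
    if missing_rule == "keep_complete_group":
        keep = keep0 & has_complete
    else:
        keep = keep0 & ~has_complete
    report = {
        "input": len(matrix),
        "removed_flagged": int(flagged.sum()),
        "removed_low_evidence": int(low_evidence.sum()),
        "removed_missing_rule": int((keep0 & ~keep).sum()),
        "retained": int(keep.sum()),
    }
    return matrix.subset(list(matrix.lfq.index[keep])), report


# ---------------------------------------------------------------------------
# growth-dependence classification
# ---------------------------------------------------------------------------

def kruskal_wallis_pair(x: Sequence[float], y: Sequence[float],
                        method: str = "asymptotic") -> float:
    """Two-sample Kruskal-Wallis p-value (rank test, tie-corrected).

    ``method="asymptotic"`` uses the chi-square approximation (as in
    scipy.stats.kruskal); ``"exact"`` enumerates all assignments of the
    pooled ranks to the two groups and reports P(H >= H_observed), which
    is preferable for very small samples.  Identical values in both
    groups give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "asymptotic":
        import warnings
        try:
            with warnings.catch_warnings():
                # fully tied inputs yield a harmless 0/0 inside the
                # statistic; the resulting NaN is mapped to p = 1 below
                warnings.simplefilter("ignore")
                p = float(stats.kruskal(x, y).pvalue)
        except ValueError:  # all values identical
            return 1.0
        return 1.0 if math.isnan(p) else p
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    h_obs = _kw_statistic(pooled, len(x))
    n = len(pooled)
    hits = total = 0
    for combo in itertools.combinations(range(n), len(x)):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        h = _kw_statistic_masked(pooled, mask)
        total += 1
        if h >= h_obs - 1e-12:
            hits += 1
    return hits / total


def _kw_statistic(pooled: np.ndarray, n1: int) -> float:
    mask = np.zeros(len(pooled), dtype=bool)
    mask[:n1] = True
    return _kw_statistic_masked(pooled, mask)


def _kw_statistic_masked(pooled: np.ndarray, mask: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H for a 2-group split of pooled data."""
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    n1 = int(mask.sum())
    n2 = n - n1
    r1 = ranks[mask].sum()
    r2 = ranks[~mask].sum()
    h = (12.0 / (n * (n + 1))
         * (r1 ** 2 / n1 + r2 ** 2 / n2)) - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie if tie > 0 else 0.0


@dataclass
class DependenceCall:
    """Growth-dependence call for one protein."""

    protein_id: str
    dependent: bool
    min_pair_p: float
    n_pairs_tested: int
    testable: bool = True


def classify_growth_dependence(matrix: IntensityMatrix, alpha: float = 0.05,
                               min_samples: int = 3,
                               method: str = "asymptotic",
                               correction: str | None = None,
                               layer: str = "lfq",
                               ) -> tuple[list[DependenceCall], dict]:
    """Call growth dependence per protein by pairwise Kruskal-Wallis tests.

    Every pair of condition groups in which the protein has at least
    ``min_samples`` non-missing values is tested; the protein is called
    dependent iff any pairwise p-value is below ``alpha``.  Following the
    original analysis no multiplicity correction is applied by default;
    ``correction="bh"`` applies Benjamini-Hochberg across all pairs and
    proteins before thresholding.  The test is rank-based, so calls are
    invariant under strictly monotone transforms of the intensities
    (applying log2 upstream changes nothing).

    Proteins with fewer than two eligible groups are marked untestable and
    excluded from the dependent/independent counts.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    data = getattr(matrix, layer)
    group_cols = {g: matrix.group_columns(g) for g in matrix.group_names}
    calls: list[DependenceCall] = []
    all_ps: list[tuple[int, int, float]] = []  # (protein idx, pair idx, p)
    per_protein_ps: list[list[float]] = []
    for pid in data.index:
        row = data.loc[pid]
        samples = {g: row[cols].dropna().to_numpy()
                   for g, cols in group_cols.items()}
        eligible = [g for g, v in samples.items() if len(v) >= min_samples]
        ps = []
        for g1, g2 in itertools.combinations(eligible, 2):
            ps.append(kruskal_wallis_pair(samples[g1], samples[g2],
                                          method=method))
        per_protein_ps.append(ps)
        if len(eligible) < 2:
            calls.append(DependenceCall(pid, False, float("nan"), 0,
                                        testable=False))
        else:
            calls.append(DependenceCall(pid, False, float(np.min(ps)),
                                        len(ps)))
    if correction == "bh":
        flat = [p for ps in per_protein_ps for p in ps]
        adj = _benjamini_hochberg(np.asarray(flat))
        pos = 0
        for call, ps in zip(calls, per_protein_ps):
            k = len(ps)
            if call.testable and k:
                call.min_pair_p = float(adj[pos:pos + k].min())
            pos += k
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    for call in calls:
        if call.testable:
            call.dependent = bool(call.min_pair_p < alpha)
    summary = {
        "total": len(calls),
        "dependent": sum(c.dependent for c in calls),
        "independent": sum(c.testable and not c.dependent for c in calls),
        "untestable": sum(not c.testable for c in calls),
        "alpha": alpha,
    }
    return calls, summary


def calls_frame(calls: Iterable[DependenceCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein_id": c.protein_id, "dependent": c.dependent,
        "min_pair_p": c.min_pair_p, "n_pairs_tested": c.n_pairs_tested,
        "testable": c.testable} for c in calls])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """k-means clustering of normalized expression profiles."""

    k: int
    assignments: pd.Series
    centroids: pd.DataFrame
    profile_matrix: pd.DataFrame
    inertia_curve: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def expression_profiles(matrix: IntensityMatrix, layer: str = "lfq",
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Per-group median profile, normalized by each protein's profile mean.

    Proteins whose profile cannot be completed (a group entirely missing,
    or a zero profile mean) are excluded and reported.
    """
    data = getattr(matrix, layer)
    med = pd.DataFrame({g: data[matrix.group_columns(g)].median(axis=1)
                        for g in matrix.group_names})
    complete = med.notna().all(axis=1) & (med.mean(axis=1) > 0)
    excluded = list(med.index[~complete])
    med = med.loc[complete]
    profiles = med.div(med.mean(axis=1), axis=0)
    return profiles, excluded


def select_k_elbow(inertia: Mapping[int, float], eps: float = 1e-3) -> int:
    """Elbow rule on the within-cluster sum of squares.

    Chooses the k after which the marginal WCSS gain collapses: the k
    maximizing the ratio of successive decrements
    ``(W(k-1) - W(k)) / (W(k) - W(k+1))``, regularized by ``eps * W(1)``
    in the denominator so that ratios deep in the noise floor cannot win.
    This locates the point of diminishing returns even when the WCSS
    decays smoothly (where the raw second difference always favours
    k = 2-3).  Degenerate data (zero WCSS at k = 1) yield k = 1; ties
    break toward the smallest k.
    """
    ks = sorted(inertia)
    if len(ks) < 3:
        return ks[0]
    w = [inertia[k] for k in ks]
    if w[0] <= eps:
        return ks[0]
    best_k, best_ratio = ks[0], -math.inf
    for i in range(1, len(ks) - 1):
        gain = w[i - 1] - w[i]
        gain_next = w[i] - w[i + 1]
        ratio = gain / (max(gain_next, 0.0) + eps * w[0])
        if ratio > best_ratio * (1 + 1e-12) + 1e-15:
            best_k, best_ratio = ks[i], ratio
    return best_k


def cluster_profiles(matrix: IntensityMatrix, k: int | None = None,
                     k_range: Sequence[int] = range(1, 13),
                     seed: int = 42, n_init: int = 50,
                     layer: str = "lfq") -> ClusterResult:
    """k-means clustering of mean-normalized median profiles.

    If ``k`` is not supplied it is chosen by the elbow rule on the
    within-cluster sum of squares over ``k_range``.  Euclidean distance,
    ``n_init`` restarts, fixed seed: deterministic.
    """
    profiles, excluded = expression_profiles(matrix, layer=layer)
    if len(profiles) == 0:
        raise ValueError("no complete profiles to cluster")
    X = profiles.to_numpy()
    inertia: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    ks = [k] if k is not None else [kk for kk in k_range
                                    if kk <= len(profiles)]
    for kk in ks:
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        km.fit(X)
        inertia[kk] = float(km.inertia_)
        fits[kk] = km
    chosen = k if k is not None else select_k_elbow(inertia)
    km = fits[chosen]
    assignments = pd.Series(km.labels_, index=profiles.index, name="cluster")
    # report centroids as the means of the members (bit-exact with the
    # invariant, rather than the k-means internal centers)
    centroids = profiles.groupby(assignments).mean()
    curve = pd.DataFrame({"k": list(inertia), "wcss": list(inertia.values())})
    return ClusterResult(k=chosen, assignments=assignments,
                         centroids=centroids, profile_matrix=profiles,
                         inertia_curve=curve, excluded=excluded)


# ---------------------------------------------------------------------------
# GO slim mapping and enrichment
# ---------------------------------------------------------------------------

def map_go_slim(annotations: Mapping[str, Iterable[str]],
                slim: Mapping[str, Iterable[str] | str],
                trivial: frozenset[str] = DEFAULT_TRIVIAL_CATEGORIES,
                ) -> tuple[dict[str, set[str]], list[str]]:
    """Map per-protein GO terms to GO-slim category sets.

    Each protein receives the union of slim categories of its terms
    (set semantics: one category counted once); categories whose name is
    in ``trivial`` (case-insensitive) are discarded, so proteins with only
    trivial annotation come out with an empty set (unannotated).  Unknown
    GO identifiers are recorded and skipped.
    """
    unknown: list[str] = []
    out: dict[str, set[str]] = {}
    for pid, terms in annotations.items():
        cats: set[str] = set()
        for term in terms:
            if term not in slim:
                unknown.append(term)
                continue
            mapped = slim[term]
            if isinstance(mapped, str):
                mapped = [mapped]
            cats.update(c for c in mapped if c.lower() not in trivial)
        out[pid] = cats
    return out, sorted(set(unknown))


@dataclass
class EnrichmentRow:
    """2x2 Fisher test of one GO-slim category vs growth dependence.

    ``a``: dependent proteins in the category, ``b``: independent in the
    category, ``c``: dependent outside, ``d``: independent outside.
    """

    term: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def enrich_go_slim(calls: Sequence[DependenceCall],
                   slim_annotations: Mapping[str, set[str]],
                   alpha: float = 0.05) -> list[EnrichmentRow]:
    """Two-sided Fisher exact test per GO-slim category.

    Only testable proteins enter the 2x2 tables; categories with zero
    annotated members are omitted.
    """
    dep = {c.protein_id for c in calls if c.testable and c.dependent}
    indep = {c.protein_id for c in calls if c.testable and not c.dependent}
    universe = dep | indep
    categories: dict[str, set[str]] = {}
    for pid, cats in slim_annotations.items():
        if pid not in universe:
            continue
        for cat in cats:
            categories.setdefault(cat, set()).add(pid)
    rows = []
    for term in sorted(categories):
        members = categories[term]
        a = len(members & dep)
        b = len(members & indep)
        c = len(dep) - a
        d = len(indep) - b
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(EnrichmentRow(term=term, a=a, b=b, c=c, d=d,
                                  odds_ratio=float(odds), p=float(p)))
    rows.sort(key=lambda r: r.p)
    return rows


def enrichment_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": r.term, "dependent_in": r.a, "independent_in": r.b,
        "dependent_out": r.c, "independent_out": r.d,
        "odds_ratio": r.odds_ratio, "p": r.p,
        "significant": r.significant} for r in rows])
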