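"""Top-p SNP screening and overlap analysis across and within populations.

SNPs enter the risk model after screening: either the ``p`` variants with
the largest absolute BLUP score from the genomic mixed model, or those with
the smallest single-SNP regression p-values. Overlap reports compare the
screened lists between populations (how transferable is the architecture?)
and between random splits of one population (how stable is screening under
resampling?), against the hypergeometric expectation for random lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .mixed_model import (
    BlupScores,
    KEig,
    blup_snp_effects,
    compute_grm,
    per_snp_regression,
    reml_fit,
)

__all__ = [
    "ScreenCriterion",
    "TopSnpList",
    "OverlapReport",
    "select_top_snps",
    "overlap_between_groups",
    "within_group_overlap",
    "screen_cohort",
    "hypergeometric_expected_overlap",
]


@dataclass
class ScreenCriterion:
    kind: str  # "abs_blup" | "pvalue"
    p: int

    def __post_init__(self) -> None:
        if self.kind not in ("abs_blup", "pvalue"):
            raise ValueError(f"unknown screening criterion {self.kind!r}")
        if self.p < 1:
            raise ValueError("p must be >= 1")


@dataclass
class TopSnpList:
    variant_ids: list[str]
    criterion: ScreenCriterion
    source: str = ""
    panel_size: int = 0

    def __post_init__(self) -> None:
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("duplicate ids in top-SNP list")


@dataclass
class OverlapReport:
    mode: str  # "between_groups" | "within_group_splits"
    list_sizes: list[int]
    pairwise_counts: dict[tuple[str, str], int]
    allway_count: int
    pairwise_proportions: dict[tuple[str, str], float]
    allway_proportion: float
    labels: list[str] = field(default_factory=list)

    @property
    def mean_pairwise_proportion(self) -> float:
        vals = list(self.pairwise_proportions.values())
        return float(np.mean(vals)) if vals else 0.0


def select_top_snps(scores, criterion: ScreenCriterion, source: str = "") -> TopSnpList:
    """Rank variants and keep the top ``p``.

    ``abs_blup`` sorts by descending absolute score; ``pvalue`` by ascending
    p. Ties are broken by (chromosome, position, id) ascending so the output
    is a pure function of the score table. Asking for more variants than are
    available returns them all with a warning.
    """
    if isinstance(scores, BlupScores):
        scores = scores.table
    df = scores.copy()
    if criterion.kind == "abs_blup":
        if "score" not in df.columns:
            raise ValueError("abs_blup criterion needs a 'score' column")
        df["_key"] = -df["score"].abs()
    else:
        if "p" not in df.columns:
            raise ValueError("pvalue criterion needs a 'p' column")
        df["_key"] = df["p"]
    df["_chrom_num"] = pd.to_numeric(df["chrom"], errors="coerce").fillna(np.inf)
    df = df.sort_values(
        ["_key", "_chrom_num", "chrom", "pos", "id"], kind="mergesort"
    )
    if criterion.p > len(df):
        import warnings

        warnings.warn(
            f"requested top {criterion.p} of only {len(df)} variants; returning all"
        )
    top = df.head(criterion.p)
    return TopSnpList(
        variant_ids=list(top["id"]),
        criterion=criterion,
        source=source,
        panel_size=len(df),
    )


def overlap_between_groups(lists: list[TopSnpList]) -> OverlapReport:
    """Exact set intersections of per-group top-p lists, proportions over p."""
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    sizes = {len(l.variant_ids) for l in lists}
    panels = {l.panel_size for l in lists}
    if len(panels) > 1:
        raise ValueError(f"lists built over different variant panels: sizes {sorted(panels)}")
    p = max(sizes)
    sets = [set(l.variant_ids) for l in lists]
    labels = [l.source or f"group{i}" for i, l in enumerate(lists)]
    pairwise_counts = {}
    pairwise_props = {}
    for (i, a), (j, b) in combinations(enumerate(sets), 2):
        c = len(a & b)
        pairwise_counts[(labels[i], labels[j])] = c
        pairwise_props[(labels[i], labels[j])] = c / p
    allway = len(set.intersection(*sets))
    return OverlapReport(
        mode="between_groups",
        list_sizes=[len(s) for s in sets],
        pairwise_counts=pairwise_counts,
        allway_count=allway,
        pairwise_proportions=pairwise_props,
        allway_proportion=allway / p,
        labels=labels,
    )


def hypergeometric_expected_overlap(p: int, n_variants: int) -> float:
    """Expected overlap proportion of two independent random top-p lists.

    Drawing two p-subsets of an n-variant panel uniformly at random, the
    intersection count is hypergeometric with mean p^2/n, i.e., an expected
    proportion of p/n.
    """
    return p / n_variants


def screen_cohort(
    g,
    phen: pd.DataFrame,
    criterion: ScreenCriterion,
    covariates: list[str] = ("age", "sex", "height", "pack_years"),
    source: str = "",
    fallback_to_pvalue: bool = True,
) -> TopSnpList:
    """Run the full screening stack on one cohort.

    abs_blup: GRM -> REML on the continuous trait with the clinical fixed
    effects -> per-SNP BLUP -> top-p. When REML puts sigma_g2 on the zero
    boundary (BLUP undefined) the cohort falls back to p-value screening if
    permitted. pvalue: single-SNP OLS with the same covariates.
    """
    y = phen["trait"].to_numpy(dtype=float)
    Z = np.column_stack(
        [np.ones(len(phen))] + [phen[c].to_numpy(dtype=float) for c in covariates]
    )
    if criterion.kind == "abs_blup":
        grm = compute_grm(g)
        eig = KEig.from_grm(grm)
        fit = reml_fit(y, Z, grm, eig=eig)
        if fit[0].sigma_g2 > 0:
            scores = blup_snp_effects(g, grm, y, Z, fit, eig=eig)
            top = select_top_snps(scores, criterion, source=source)
            top.panel_size = g.n_variants
            return top
        if not fallback_to_pvalue:
            raise ValueError(f"{source or 'cohort'}: sigma_g2 at zero boundary, BLUP undefined")
        criterion = ScreenCriterion("pvalue", criterion.p)
    assoc = per_snp_regression(g, y, Z)
    top = select_top_snps(assoc, criterion, source=source)
    top.panel_size = g.n_variants
    return top


def within_group_overlap(
    g,
    phen: pd.DataFrame,
    criterion: ScreenCriterion,
    n_splits: int = 3,
    seed: int = 0,
    covariates: list[str] = ("age", "sex", "height", "pack_years"),
) -> OverlapReport:
    """Screening stability within one cohort.

    Partitions the cohort into ``n_splits`` disjoint equal-size subgroups at
    random and runs the full screening stack independently in each (GRM,
    REML and BLUP are recomputed per subgroup, so no information crosses
    subgroup boundaries), then reports the overlap of the resulting lists.
    """
    n = g.n_samples
    size = n // n_splits
    if size < 30:
        raise ValueError("subgroups too small for mixed-model screening")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    lists = []
    for s in range(n_splits):
        idx = np.sort(perm[s * size : (s + 1) * size])
        sub_g = g.subset_samples(idx)
        sub_p = phen.iloc[idx].reset_index(drop=True)
        try:
            lists.append(
                screen_cohort(sub_g, sub_p, criterion, covariates, source=f"split{s}")
            )
        except Exception as exc:  # propagate with subgroup label
            raise RuntimeError(f"screening failed in subgroup split{s}") from exc
    report = overlap_between_groups(lists)
    report.mode = "within_group_splits"
    return report
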