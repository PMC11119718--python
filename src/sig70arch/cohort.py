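"""Cohort-level distribution statistics for classified sigma70 homologs.

Counts of homologs per family per genome are assembled into a complete
genome x family matrix and analyzed against genome metadata (taxonomic
order, morphotype U/F/H, number of protein-coding genes).  Group comparisons
follow a normality-gated cascade: both groups are screened with the
Shapiro-Wilk test at alpha = 0.05; if both pass, a two-sided two-sample
Student t-test is used, otherwise the two-sided Wilcoxon-Mann-Whitney test.
Significance stars follow the usual convention (* p<0.05, ** p<0.01,
*** p<0.001).  No multiple-testing correction is applied to the stars
(mirroring common practice for these cohort reports); a Benjamini-Hochberg
adjusted column is emitted alongside for transparency.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .architecture import DEFAULT_VOCABULARY, DomainVocabulary

__all__ = [
    "GenomeRecord",
    "CountMatrix",
    "GroupComparison",
    "MorphotypeReport",
    "SizeCorrelation",
    "AccessorySurvey",
    "build_count_matrix",
    "bin_for_heatmap",
    "merge_small_orders",
    "compare_two_groups",
    "stars_for_p",
    "family_morphotype_tests",
    "counts_vs_genome_size",
    "accessory_survey",
    "plot_heatmap",
]

MORPHOTYPES = ("U", "F", "H")


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one genome: taxonomic order, morphotype and CDS count."""

    genome_id: str
    taxonomic_order: str
    morphotype: str
    cds_count: int

    def __post_init__(self) -> None:
        if self.morphotype not in MORPHOTYPES:
            raise ValueError(f"morphotype must be one of {MORPHOTYPES}")
        if self.cds_count < 0:
            raise ValueError("cds_count must be >= 0")


@dataclass
class CountMatrix:
    """Genome x family homolog counts with margins.

    ``counts`` is a complete integer DataFrame (zero cells included), indexed
    by genome id with family labels as columns.
    """

    counts: pd.DataFrame

    @property
    def row_totals(self) -> pd.Series:
        """Total homologs per genome."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        """Total homologs per family."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


def _normalize_genomes(genomes: pd.DataFrame | Iterable[GenomeRecord]) -> pd.DataFrame:
    if isinstance(genomes, pd.DataFrame):
        df = genomes.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "genome_id": g.genome_id,
                    "order": g.taxonomic_order,
                    "morphotype": g.morphotype,
                    "cds_count": g.cds_count,
                }
                for g in genomes
            ]
        )
    return df


def build_count_matrix(
    units: pd.DataFrame,
    genomes: pd.DataFrame | Iterable[GenomeRecord],
) -> CountMatrix:
    """Count homologs per (genome, family), completing zero rows and cells.

    ``units`` needs ``genome_id`` and ``family`` columns (one row per
    homolog).  Every genome of the metadata table gets a row even when it has
    no homologs; a unit referencing a genome absent from the metadata is an
    error listing the offenders.
    """
    gdf = _normalize_genomes(genomes)
    known = set(gdf["genome_id"].astype(str))
    if not units.empty:
        orphans = sorted(set(units["genome_id"].astype(str)) - known)
        if orphans:
            raise ValueError(f"units reference unknown genomes: {orphans}")
    families = sorted(units["family"].astype(str).unique()) if not units.empty else []
    mat = pd.DataFrame(
        0, index=sorted(known), columns=families, dtype=int
    )
    if not units.empty:
        tallied = units.groupby(["genome_id", "family"]).size()
        for (gid, fam), n in tallied.items():
            mat.loc[str(gid), str(fam)] = int(n)
    mat.index.name = "genome_id"
    return CountMatrix(counts=mat)


def bin_for_heatmap(matrix: CountMatrix) -> pd.DataFrame:
    """Bin counts into the heatmap scale {0, 1, 2, 3+} (cell -> min(cell, 3))."""
    return matrix.counts.clip(upper=3)


def merge_small_orders(
    genomes: pd.DataFrame,
    min_n: int = 10,
    label: str = "Others",
) -> pd.DataFrame:
    """Relabel taxonomic orders with fewer than ``min_n`` genomes as ``label``."""
    df = genomes.copy()
    if df.empty:
        return df
    sizes = df.groupby("order")["genome_id"].transform("size")
    df.loc[sizes < min_n, "order"] = label
    return df


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupComparison:
    test_name: str  # "t-test" or "wilcoxon"
    statistic: float
    p_value: float
    stars: str
    shapiro_p: tuple[float, float]


def _shapiro_p(values: np.ndarray) -> float:
    # constant samples are trivially non-normal for the cascade's purposes
    if np.ptp(values) == 0:
        return 0.0
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def _mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney U.

    Exact null distribution for small tie-free samples (both n <= 20), the
    normal approximation with tie correction otherwise.
    """
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_two_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated two-group comparison (two-sided).

    Shapiro-Wilk on each group at ``alpha``; both normal -> Student two-sample
    t-test, otherwise Wilcoxon-Mann-Whitney.  Requires at least 3 values per
    group.  The branch actually taken is recorded in ``test_name`` together
    with the two Shapiro p-values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if np.ptp(np.concatenate([a, b])) == 0:
        # all observations identical: no evidence of any difference
        return GroupComparison("degenerate", 0.0, 1.0, "", (0.0, 0.0))
    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa > alpha and pb > alpha:
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
        name = "t-test"
    else:
        stat, p = _mannwhitney(a, b)
        name = "wilcoxon"
    return GroupComparison(name, stat, p, stars_for_p(p), (pa, pb))


@dataclass
class MorphotypeReport:
    """Per-family morphotype comparisons.

    ``pairwise`` holds all available U/F/H pairwise cascade tests per family
    (with a BH-adjusted p column across the whole report); ``h_vs_rest``
    holds the one-sample t-test of heterocyst-forming (H) per-genome counts
    against the non-H group mean, with the direction of the difference.
    """

    pairwise: pd.DataFrame
    h_vs_rest: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def family_morphotype_tests(
    matrix: CountMatrix,
    genomes: pd.DataFrame | Iterable[GenomeRecord],
    families: Sequence[str] | None = None,
    alpha: float = 0.05,
    reference: str = "non-H-mean",
) -> MorphotypeReport:
    """All pairwise U/F/H comparisons per family, plus H-vs-rest enrichment.

    For each family the per-genome homolog counts are compared between every
    pair of morphotypes present (cascade of :func:`compare_two_groups`), and
    the H group is tested against the mean of the pooled non-H genomes with a
    two-sided one-sample t-test; the sign of (H mean - reference) gives the
    enrichment direction.  Missing morphotypes or groups smaller than 3
    genomes degrade to the available pairs with a warning.
    """
    gdf = _normalize_genomes(genomes).set_index("genome_id")
    fams = list(families) if families is not None else list(matrix.counts.columns)
    morphs = gdf.loc[matrix.counts.index, "morphotype"]
    present = [m for m in MORPHOTYPES if (morphs == m).sum() > 0]
    warn: list[str] = []
    if len(present) < 2:
        warn.append(f"only morphotypes {present} present; pairwise report empty")
    pairwise_rows = []
    h_rows = []
    for fam in fams:
        col = matrix.counts[fam]
        groups = {m: col[morphs == m].to_numpy(dtype=float) for m in present}
        for ma, mb in itertools.combinations(present, 2):
            if len(groups[ma]) < 3 or len(groups[mb]) < 3:
                warn.append(f"{fam}: pair {ma}/{mb} skipped (group smaller than 3)")
                continue
            cmp = compare_two_groups(groups[ma], groups[mb], alpha=alpha)
            pairwise_rows.append(
                {
                    "family": fam,
                    "group_a": ma,
                    "group_b": mb,
                    "n_a": len(groups[ma]),
                    "n_b": len(groups[mb]),
                    "test": cmp.test_name,
                    "statistic": cmp.statistic,
                    "p_value": cmp.p_value,
                    "stars": cmp.stars,
                }
            )
        # H-group vs non-H reference mean (one-sample t-test, two-sided)
        h_vals = col[morphs == "H"].to_numpy(dtype=float)
        rest = col[morphs != "H"].to_numpy(dtype=float)
        if len(h_vals) < 3 or len(rest) == 0:
            warn.append(f"{fam}: H-vs-rest test skipped (insufficient genomes)")
            continue
        ref = float(np.mean(rest)) if reference == "non-H-mean" else float(reference)
        if np.ptp(h_vals) == 0:
            stat, p = 0.0, (1.0 if h_vals[0] == ref else 0.0)
        else:
            res = stats.ttest_1samp(h_vals, popmean=ref)
            stat, p = float(res.statistic), float(res.pvalue)
        diff = float(np.mean(h_vals) - ref)
        h_rows.append(
            {
                "family": fam,
                "n_h": len(h_vals),
                "h_mean": float(np.mean(h_vals)),
                "reference_mean": ref,
                "statistic": stat,
                "p_value": p,
                "direction": "H>rest" if diff > 0 else ("H<rest" if diff < 0 else "equal"),
                "stars": stars_for_p(p),
            }
        )
    pairwise = pd.DataFrame(
        pairwise_rows,
        columns=[
            "family", "group_a", "group_b", "n_a", "n_b",
            "test", "statistic", "p_value", "stars",
        ],
    )
    if not pairwise.empty:
        pairwise["p_bh"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    else:
        pairwise["p_bh"] = pd.Series(dtype=float)
    h_vs_rest = pd.DataFrame(
        h_rows,
        columns=[
            "family", "n_h", "h_mean", "reference_mean",
            "statistic", "p_value", "direction", "stars",
        ],
    )
    return MorphotypeReport(pairwise=pairwise, h_vs_rest=h_vs_rest, warnings=warn)


@dataclass(frozen=True)
class SizeCorrelation:
    table: pd.DataFrame  # genome_id, cds_count, total_homologs
    rho: float
    p_value: float
    n: int
    low_n: bool


def counts_vs_genome_size(
    matrix: CountMatrix,
    genomes: pd.DataFrame | Iterable[GenomeRecord],
) -> SizeCorrelation:
    """Per-genome (CDS count, total homologs) pairs and their Spearman rank
    correlation; flagged ``low_n`` below 10 genomes."""
    gdf = _normalize_genomes(genomes).set_index("genome_id")
    table = pd.DataFrame(
        {
            "genome_id": matrix.counts.index,
            "cds_count": gdf.loc[matrix.counts.index, "cds_count"].to_numpy(),
            "total_homologs": matrix.row_totals.to_numpy(),
        }
    )
    rho, p = stats.spearmanr(table["cds_count"], table["total_homologs"])
    return SizeCorrelation(
        table=table, rho=float(rho), p_value=float(p), n=len(table), low_n=len(table) < 10
    )


@dataclass
class AccessorySurvey:
    """Per-clade prevalence of an accessory domain among sigma70 proteins.

    ``per_clade``: one row per clade with the percentage of genomes carrying
    at least one protein with the domain and the percentage of those proteins
    that also carry an essential sigma70 domain.  ``breakdown``: family
    composition of the domain-carrying proteins per clade, with ``Ud`` for
    proteins containing only accessory domains.
    """

    domain: str
    per_clade: pd.DataFrame
    breakdown: pd.DataFrame


def accessory_survey(
    proteins: pd.DataFrame,
    genomes: pd.DataFrame,
    domain: str = "DUF6596",
    min_clade_size: int = 15,
    catch_all: str = "Other Bacteria",
    vocab: DomainVocabulary = DEFAULT_VOCABULARY,
) -> AccessorySurvey:
    """Survey an accessory domain (default DUF6596) across clades.

    ``proteins`` carries one row per protein with ``genome_id``,
    ``protein_id``, ``architecture_string`` and (nullable) ``family``;
    accessory-only proteins should have an empty/NaN family and are reported
    as ``Ud``.  ``genomes`` needs a ``clade`` column; genomes with unknown
    clades, and clades with fewer than ``min_clade_size`` genomes, are merged
    into ``catch_all`` before percentages are computed.
    """
    gdf = genomes.copy()
    if "clade" not in gdf.columns:
        raise ValueError("genomes table needs a 'clade' column for the survey")
    gdf["clade"] = gdf["clade"].fillna(catch_all).astype(str)
    sizes = gdf.groupby("clade")["genome_id"].transform("size")
    gdf.loc[sizes < min_clade_size, "clade"] = catch_all
    clade_of = dict(zip(gdf["genome_id"].astype(str), gdf["clade"]))

    prot = proteins.copy()
    tokens = prot["architecture_string"].astype(str).str.split("*")
    prot["_has_domain"] = tokens.map(lambda ts: domain in ts)
    prot["_has_essential"] = tokens.map(lambda ts: any(vocab.is_essential(t) for t in ts))
    prot["_clade"] = prot["genome_id"].astype(str).map(clade_of)
    unknown = prot["_clade"].isna()
    prot.loc[unknown, "_clade"] = catch_all

    rows = []
    breakdown_rows = []
    for clade, cg in gdf.groupby("clade"):
        n_genomes = len(cg)
        sub = prot[(prot["_clade"] == clade) & prot["_has_domain"]]
        genomes_with = sub["genome_id"].nunique()
        n_prot = len(sub)
        n_sigma = int(sub["_has_essential"].sum())
        rows.append(
            {
                "clade": clade,
                "n_genomes": n_genomes,
                "genomes_with_domain": genomes_with,
                "pct_genomes_with_domain": 100.0 * genomes_with / n_genomes if n_genomes else 0.0,
                "n_domain_proteins": n_prot,
                "pct_in_sigma70": 100.0 * n_sigma / n_prot if n_prot else 0.0,
            }
        )
        fam = sub["family"].where(sub["_has_essential"], other="Ud")
        fam = fam.fillna("Ud").replace("", "Ud")
        for label, n in fam.value_counts().sort_index().items():
            breakdown_rows.append(
                {
                    "clade": clade,
                    "family": label,
                    "n": int(n),
                    "pct": 100.0 * n / n_prot,
                }
            )
    per_clade = pd.DataFrame(
        rows,
        columns=[
            "clade", "n_genomes", "genomes_with_domain", "pct_genomes_with_domain",
            "n_domain_proteins", "pct_in_sigma70",
        ],
    ).sort_values("clade").reset_index(drop=True)
    breakdown = pd.DataFrame(
        breakdown_rows, columns=["clade", "family", "n", "pct"]
    )
    return AccessorySurvey(domain=domain, per_clade=per_clade, breakdown=breakdown)


def plot_heatmap(
    matrix: CountMatrix,
    genomes: pd.DataFrame | Iterable[GenomeRecord],
    path: str,
) -> None:
    """Render the binned genome x family heatmap (rows grouped by morphotype
    then taxonomic order) to an image file.  Requires matplotlib/seaborn."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    gdf = _normalize_genomes(genomes).set_index("genome_id")
    binned = bin_for_heatmap(matrix)
    order = (
        gdf.loc[binned.index]
        .sort_values(["morphotype", "order"])
        .index
    )
    binned = binned.loc[order]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * binned.shape[1]), max(4, 0.08 * len(binned))))
    sns.heatmap(
        binned,
        ax=ax,
        cmap=sns.color_palette("Blues", 4),
        cbar_kws={"ticks": [0, 1, 2, 3], "label": "homologs (3 = >=3)"},
        yticklabels=False,
    )
    ax.set_xlabel("family")
    ax.set_ylabel("genome (grouped by morphotype, order)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
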