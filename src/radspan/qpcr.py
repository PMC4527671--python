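"""Reference-gene stability, efficiency-corrected quantification, and DE calls.

Stability of candidate reference genes is scored by four methods — the
pairwise-SD "delta-Ct" comparison, BestKeeper-style descriptive statistics,
a NormFinder-style intra/inter-group variance decomposition, and geNorm's
pairwise-variation M value with stepwise exclusion — and the four ranks are
averaged into a consensus rating from which the reference set is chosen.

Relative expression of gene i in sample j is efficiency corrected and
normalised to the geometric mean of the n chosen reference genes:

    R_ij = E_i^(-Ct_ij) / ( prod_k E_rk^(-Ct_rk,j) )^(1/n)

With all efficiencies equal to 2 and a single reference this is the familiar
2^(-dCt) quantity.  Fold changes between an exposed and a control group are
formed per biological replicate, FC_b = R_exp,b / R_ctrl,b, summarised as the
mean and SD of log2 FC, with a two-sided Welch t-test on log2 R as the
default significance test.  A contrast is called differentially expressed
when |mean log2FC| >= 1, p < 0.05, and the relative SD filter passes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "StabilityReport",
    "ExpressionContrast",
    "collapse_technical",
    "stability_delta_ct",
    "stability_bestkeeper",
    "stability_normfinder",
    "stability_genorm",
    "consensus_ranking",
    "relative_expression",
    "fold_change_contrast",
    "call_de",
]

TECH_SD_FLAG_CYCLES = 0.5  # technical triplicates wider than this are flagged


@dataclass
class CtTable:
    """Gene x sample Ct matrix (technical replicates collapsed).

    ``ct`` is indexed by gene with one column per sample; ``sample_meta`` is
    indexed by sample id and carries at least 'group' and 'bio_rep';
    ``efficiencies`` maps gene -> per-cycle amplification factor E.
    """

    ct: pd.DataFrame
    sample_meta: pd.DataFrame
    efficiencies: pd.Series
    reference_genes: list[str] = field(default_factory=list)
    flags: pd.DataFrame | None = None   # (gene, sample) rows flagged at collapse
    min_efficiency: float = 1.9

    def __post_init__(self) -> None:
        missing = [g for g in self.ct.index if g not in self.efficiencies.index]
        if missing:
            raise ValueError(f"efficiency missing for genes: {missing}")
        eff = self.efficiencies.loc[self.ct.index]
        bad = eff[(eff <= 1.0) | (eff > 2.2)]
        if len(bad):
            raise ValueError(f"efficiencies outside (1, 2.2]: {dict(bad)}")
        low = eff[eff <= self.min_efficiency]
        if len(low):
            raise ValueError(
                f"efficiencies at or below {self.min_efficiency} (override via "
                f"min_efficiency): {dict(low)}"
            )
        for ref in self.reference_genes:
            if ref not in self.ct.index:
                raise ValueError(f"reference gene {ref!r} absent from the Ct table")
            if self.ct.loc[ref].isna().any():
                raise ValueError(f"reference gene {ref!r} has missing Ct values")

    def samples_of(self, group: str) -> pd.DataFrame:
        sub = self.sample_meta[self.sample_meta["group"] == group]
        if sub.empty:
            raise ValueError(f"no samples in group {group!r}")
        return sub.sort_values("bio_rep")


def collapse_technical(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates per (gene, sample).

    Expects long-format columns gene, sample_id, ct (extra columns pass
    through the flag table).  Returns (wide gene x sample mean-Ct matrix,
    per-(gene, sample) QC table with n, mean, sd, and a flag for technical
    SD > 0.5 cycles or a missing reaction).
    """
    required = {"gene", "sample_id", "ct"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw Ct table must have columns {sorted(required)}")
    grouped = raw.groupby(["gene", "sample_id"])["ct"]
    qc = grouped.agg(n="count", mean_ct="mean", sd_ct=lambda s: s.std(ddof=1)).reset_index()
    qc["sd_ct"] = qc["sd_ct"].fillna(0.0)
    qc["flagged"] = (qc["sd_ct"] > TECH_SD_FLAG_CYCLES) | (qc["n"] < 1)
    wide = qc.pivot(index="gene", columns="sample_id", values="mean_ct")
    missing = wide.isna()
    if missing.any().any():
        for gene, row in missing.iterrows():
            for sample in row[row].index:
                qc = pd.concat([qc, pd.DataFrame([{
                    "gene": gene, "sample_id": sample, "n": 0,
                    "mean_ct": np.nan, "sd_ct": np.nan, "flagged": True}])],
                    ignore_index=True)
    return wide, qc


# ---------------------------------------------------------------------------
# stability methods (lower score = more stable throughout)
# ---------------------------------------------------------------------------

def _check_candidates(ct: pd.DataFrame, candidates: Sequence[str], min_genes: int) -> pd.DataFrame:
    missing = [g for g in candidates if g not in ct.index]
    if missing:
        raise ValueError(f"candidate genes absent from Ct table: {missing}")
    if len(candidates) < min_genes:
        raise ValueError(f"need at least {min_genes} candidate genes")
    sub = ct.loc[list(candidates)]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    return sub


def stability_delta_ct(ct: pd.DataFrame, candidates: Sequence[str]) -> pd.Series:
    """Mean pairwise SD of Ct differences (the comparative delta-Ct method)."""
    sub = _check_candidates(ct, candidates, 2)
    scores = {}
    for g in candidates:
        sds = [float((sub.loc[g] - sub.loc[h]).std(ddof=1)) for h in candidates if h != g]
        scores[g] = float(np.mean(sds))
    return pd.Series(scores, name="delta_ct")


def stability_bestkeeper(ct: pd.DataFrame, candidates: Sequence[str]) -> pd.DataFrame:
    """BestKeeper-style descriptives: SD of Ct (primary score), CV%, and the
    correlation of each gene with the per-sample mean Ct of all candidates."""
    sub = _check_candidates(ct, candidates, 2)
    index_ct = sub.mean(axis=0)
    rows = {}
    for g in candidates:
        x = sub.loc[g]
        sd = float(x.std(ddof=1))
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(x, index_ct)[0, 1]) if x.std() > 0 else np.nan
        rows[g] = {"sd": sd, "cv_pct": 100.0 * sd / float(x.mean()), "r_index": r}
    return pd.DataFrame(rows).T[["sd", "cv_pct", "r_index"]]


def stability_normfinder(
    ct: pd.DataFrame,
    candidates: Sequence[str],
    efficiencies: pd.Series,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> pd.Series:
    """Model-based stability on log2 expression (-Ct * log2 E).

    Per-sample means across candidates are removed (sample loading), then the
    centred values are decomposed into within-group variance and a
    between-group variance component; the stability value is
    sqrt(max(0, between-group component) + mean within-group variance).
    With a single group (or ``groups`` omitted) this reduces to the SD of the
    centred log2 expression.
    """
    sub = _check_candidates(ct, candidates, 2)
    log2e = np.log2(efficiencies.loc[list(candidates)].astype(float))
    x = -sub.mul(log2e, axis=0)            # log2 expression
    z = x - x.mean(axis=0)                 # remove per-sample loading

    if groups is None:
        group_of = pd.Series("all", index=sub.columns)
    else:
        group_of = pd.Series(groups).reindex(sub.columns)
        if group_of.isna().any():
            raise ValueError("every sample needs a group label")
    glabels = group_of.unique()
    for g in glabels:
        if (group_of == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    scores = {}
    for gene in candidates:
        zi = z.loc[gene]
        if len(glabels) == 1:
            scores[gene] = float(zi.std(ddof=1))
            continue
        means, variances, sizes = [], [], []
        for g in glabels:
            vals = zi[group_of == g]
            means.append(float(vals.mean()))
            variances.append(float(vals.var(ddof=1)))
            sizes.append(len(vals))
        means, variances, sizes = np.array(means), np.array(variances), np.array(sizes)
        between = max(0.0, float(np.var(means, ddof=1)) - float(np.mean(variances / sizes)))
        scores[gene] = math.sqrt(between + float(np.mean(variances)))
    return pd.Series(scores, name="normfinder")


def stability_genorm(
    ct: pd.DataFrame, candidates: Sequence[str], efficiencies: pd.Series
) -> tuple[pd.Series, list[str]]:
    """geNorm M values and stepwise-exclusion ranking.

    Relative quantities Q = E^(minCt - Ct); for each gene pair the SD over
    samples of log2(Q_j/Q_k) is the pairwise variation V, and M_j is the mean
    V against all partners.  The gene with the highest M is repeatedly
    excluded; the returned ranking lists genes from most to least stable,
    with the final two genes being indistinguishable by construction.
    """
    sub = _check_candidates(ct, candidates, 3)
    eff = efficiencies.loc[list(candidates)].astype(float)
    log2q = {}
    for g in candidates:
        # log2 Q = (minCt - Ct) * log2(E)
        log2q[g] = (sub.loc[g].min() - sub.loc[g]) * math.log2(eff[g])
    log2q = pd.DataFrame(log2q).T  # genes x samples

    def m_values(genes: list[str]) -> pd.Series:
        m = {}
        for g in genes:
            vs = [float((log2q.loc[g] - log2q.loc[h]).std(ddof=1)) for h in genes if h != g]
            m[g] = float(np.mean(vs))
        return pd.Series(m)

    full_m = m_values(list(candidates))
    remaining = list(candidates)
    excluded: list[str] = []
    while len(remaining) > 2:
        m = m_values(remaining)
        worst = m.sort_values(ascending=False).index[0]
        # deterministic tie-break: among ties, drop the alphabetically last
        ties = m[np.isclose(m, m.max())].index.tolist()
        worst = sorted(ties)[-1]
        remaining.remove(worst)
        excluded.append(worst)
    ranking = sorted(remaining) + list(reversed(excluded))
    return full_m.rename("genorm_m"), ranking


@dataclass
class StabilityReport:
    """Four-method stability scores, per-method ranks, and the consensus."""

    scores: pd.DataFrame       # genes x methods raw scores
    ranks: pd.DataFrame        # genes x methods ranks (1 = most stable)
    consensus: pd.Series       # mean rank per gene, ascending = better
    selected: list[str]        # chosen reference set


def consensus_ranking(
    ct: pd.DataFrame,
    candidates: Sequence[str],
    efficiencies: pd.Series,
    groups: Mapping[str, str] | pd.Series | None = None,
    n_ref: int = 2,
) -> StabilityReport:
    """Run all four stability methods and average their ranks.

    Ranks are 1 = most stable with average ranks on ties; geNorm ranks come
    from its exclusion order (the final pair sharing rank 1.5).  The top
    ``n_ref`` genes by consensus (alphabetical tie-break) become the selected
    reference set.
    """
    candidates = sorted(candidates)
    d = stability_delta_ct(ct, candidates)
    bk = stability_bestkeeper(ct, candidates)["sd"]
    nf = stability_normfinder(ct, candidates, efficiencies, groups)
    gm, g_order = stability_genorm(ct, candidates, efficiencies)

    genorm_rank = pd.Series(index=candidates, dtype=float)
    for pos, gene in enumerate(g_order, start=1):
        genorm_rank[gene] = float(pos)
    genorm_rank[g_order[0]] = genorm_rank[g_order[1]] = 1.5  # final pair ties

    scores = pd.DataFrame({"delta_ct": d, "bestkeeper_sd": bk,
                           "normfinder": nf, "genorm_m": gm}).loc[candidates]
    ranks = pd.DataFrame({
        "delta_ct": d.rank(method="average"),
        "bestkeeper_sd": bk.rank(method="average"),
        "normfinder": nf.rank(method="average"),
        "genorm_m": genorm_rank,
    }).loc[candidates]
    consensus = ranks.mean(axis=1).rename("consensus_rank")
    order = sorted(candidates, key=lambda g: (consensus[g], g))
    return StabilityReport(scores=scores, ranks=ranks, consensus=consensus,
                           selected=order[:n_ref])


# ---------------------------------------------------------------------------
# efficiency-corrected quantification and differential-expression calling
# ---------------------------------------------------------------------------

def relative_expression(table: CtTable, gene: str, sample: str) -> float:
    """R = E_i^(-Ct_ij) normalised by the geometric mean of the references."""
    if not table.reference_genes:
        raise ValueError("no reference genes designated")
    if gene not in table.ct.index:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    ct_ij = table.ct.at[gene, sample]
    if pd.isna(ct_ij):
        raise ValueError(f"missing Ct for ({gene!r}, {sample!r})")
    log_num = -float(ct_ij) * math.log(float(table.efficiencies[gene]))
    log_refs = []
    for ref in table.reference_genes:
        ct_r = table.ct.at[ref, sample]
        if pd.isna(ct_r):
            raise ValueError(f"missing reference Ct for ({ref!r}, {sample!r})")
        log_refs.append(-float(ct_r) * math.log(float(table.efficiencies[ref])))
    return math.exp(log_num - float(np.mean(log_refs)))


@dataclass
class ExpressionContrast:
    gene: str
    exposed_group: str
    control_group: str
    r_exposed: np.ndarray
    r_control: np.ndarray
    log2_fc: np.ndarray          # per paired replicate
    mean_log2_fc: float
    sd_log2_fc: float
    p_value: float
    de: bool | None = None
    extra: dict = field(default_factory=dict)


def fold_change_contrast(
    table: CtTable,
    gene: str,
    exposed_group: str,
    control_group: str,
    pairing: str = "index",
    p_test: str = "welch",
) -> ExpressionContrast:
    """Replicate-wise fold change of one gene between two groups.

    ``pairing='index'`` divides exposed replicate b by control replicate b
    (requires equal replicate counts); ``pairing='all_pairs'`` uses every
    exposed/control combination.  The p-value is a two-sided Welch t-test on
    log2 relative expression between the two groups (``p_test='welch'``) or
    a Mann-Whitney U (``p_test='mannwhitney'``).
    """
    exp_samples = table.samples_of(exposed_group).index.tolist()
    ctl_samples = table.samples_of(control_group).index.tolist()
    r_exp = np.array([relative_expression(table, gene, s) for s in exp_samples])
    r_ctl = np.array([relative_expression(table, gene, s) for s in ctl_samples])

    if pairing == "index":
        if len(r_exp) != len(r_ctl):
            raise ValueError("index pairing requires equal replicate counts")
        fc = r_exp / r_ctl
    elif pairing == "all_pairs":
        fc = np.array([e / c for e, c in itertools.product(r_exp, r_ctl)])
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    log2fc = np.log2(fc)

    le, lc = np.log2(r_exp), np.log2(r_ctl)
    if p_test == "welch":
        p = float(stats.ttest_ind(le, lc, equal_var=False).pvalue)
    elif p_test == "mannwhitney":
        p = float(stats.mannwhitneyu(le, lc, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown p_test {p_test!r}")
    if math.isnan(p):  # zero variance in both groups
        p = 1.0 if np.allclose(le.mean(), lc.mean()) else 0.0

    sd = float(np.std(log2fc, ddof=1)) if len(log2fc) > 1 else 0.0
    return ExpressionContrast(
        gene=gene, exposed_group=exposed_group, control_group=control_group,
        r_exposed=r_exp, r_control=r_ctl, log2_fc=log2fc,
        mean_log2_fc=float(log2fc.mean()), sd_log2_fc=sd, p_value=p,
        extra={"pairing": pairing, "p_test": p_test},
    )


def call_de(
    contrasts: Sequence[ExpressionContrast],
    min_abs_log2fc: float = 1.0,
    alpha: float = 0.05,
    rel_sd_threshold: float = 0.05,
) -> list[ExpressionContrast]:
    """Flag differential expression: fold, significance, and variability filters.

    A contrast is DE iff |mean log2FC| >= min_abs_log2fc, p < alpha, and
    SD(log2FC)/|mean log2FC| <= rel_sd_threshold.  The default threshold of
    0.05 ("SD more than 5% of the mean excludes") is deliberately strict and
    is configurable.
    """
    out = []
    for c in contrasts:
        mean = c.mean_log2_fc
        rel_sd = c.sd_log2_fc / abs(mean) if mean != 0 else math.inf
        c.de = bool(abs(mean) >= min_abs_log2fc and c.p_value < alpha
                    and rel_sd <= rel_sd_threshold)
        c.extra["rel_sd"] = rel_sd
        out.append(c)
    return out
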