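"""Expression normalization, diversity statistics and threshold-based
differential transcript expression/usage.

Full-length read counts are normalized to transcripts per million (TPM =
count / per-sample total x 10^6).  Differential transcript expression
(DTE) between two groups uses a two-sided Wilcoxon rank-sum test on TPM
(exact null distribution for small tie-free samples, mid-rank normal
approximation with continuity correction otherwise).  Differential
transcript usage (DTU) between conditions with replicates calls a gene
when two of its transcripts are significantly regulated in opposite
directions, each with a mean TPM difference above 20; between conditions
without replication a fold-change rule (>= 4-fold with pseudocount 1 and
absolute difference > 20 TPM) is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError

DTE_ALPHA = 0.05
DTU_MIN_DELTA_TPM = 20.0
REGION_MIN_FOLD_CHANGE = 4.0
REGION_MIN_DELTA_TPM = 20.0
REGION_PSEUDOCOUNT = 1.0
HI_EXPR_LOG10_TPM = 2.5


# ---------------------------------------------------------------------------
# normalization


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """TPM per transcript per sample; every column sums to 10^6."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"zero-total sample column(s): {list(zero.index)}"
        )
    return counts / totals * 1e6


def gene_aggregate(
    counts: pd.DataFrame,
    classification: pd.DataFrame,
    drop_monoexonic: bool = True,
) -> pd.DataFrame:
    """Gene-level counts: per-gene sum of member transcript counts.

    Mono-exonic transcripts are excluded when ``drop_monoexonic``; fusion
    transcripts (multiple associated genes) are excluded from gene
    aggregation.  Every counted transcript must appear in the
    classification.
    """
    cls = classification.set_index("transcript_id")
    missing = counts.index.difference(cls.index)
    if len(missing):
        raise ValidationError(
            f"transcripts absent from classification: {list(missing)[:5]}"
        )
    cls = cls.loc[counts.index]
    keep = cls["category"] != "fusion"
    if drop_monoexonic:
        keep &= cls["n_exons"] > 1
    keep &= cls["associated_genes"].astype(str).str.len() > 0
    sub = counts.loc[keep]
    genes = cls.loc[keep, "associated_genes"].astype(str)
    return sub.groupby(genes).sum()


# ---------------------------------------------------------------------------
# diversity


def diversity_stats(
    classification: pd.DataFrame,
    gene_tpm: pd.DataFrame | None = None,
    hi_expr_log10tpm: float = HI_EXPR_LOG10_TPM,
) -> dict[str, object]:
    """Per-gene isoform counts and their correlation with gene length and
    exon count.

    Gene length and exon count are taken from the representative longest
    detected transcript of each gene.  Pearson correlations are computed
    on (isoform count, log10 gene length) and (isoform count, exon
    count), over all genes and restricted to highly expressed genes
    (mean gene TPM above ``hi_expr_log10tpm`` in log10) when expression is
    supplied.  Correlations are absent (None) for fewer than 3 genes or
    constant vectors.
    """
    cls = classification[classification["associated_genes"].astype(str) != ""]
    cls = cls[cls["category"] != "fusion"]
    gene = cls.groupby("associated_genes").agg(
        n_isoforms=("transcript_id", "size"),
        length=("length", "max"),
    )
    # exon count of the representative longest transcript
    longest = cls.sort_values("length", ascending=False).drop_duplicates(
        "associated_genes"
    )
    gene["n_exons"] = longest.set_index("associated_genes")["n_exons"]

    def corr(x: pd.Series, y: pd.Series) -> float | None:
        if len(x) < 3 or x.nunique() < 2 or y.nunique() < 2:
            return None
        return float(stats.pearsonr(x, y)[0])

    out: dict[str, object] = {
        "per_gene": gene,
        "n_genes": len(gene),
        "genes_gt1_isoform": int((gene["n_isoforms"] > 1).sum()),
        "genes_gt10_isoforms": int((gene["n_isoforms"] > 10).sum()),
        "corr_length": corr(gene["n_isoforms"], np.log10(gene["length"])),
        "corr_exons": corr(gene["n_isoforms"], gene["n_exons"]),
        "corr_length_hi": None,
        "corr_exons_hi": None,
    }
    if gene_tpm is not None:
        mean_tpm = gene_tpm.mean(axis=1)
        hi = gene.index.intersection(
            mean_tpm[np.log10(mean_tpm.clip(lower=1e-12)) > hi_expr_log10tpm].index
        )
        sub = gene.loc[hi]
        out["corr_length_hi"] = corr(sub["n_isoforms"], np.log10(sub["length"]))
        out["corr_exons_hi"] = corr(sub["n_isoforms"], sub["n_exons"])
    return out


# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefactionCurve:
    depths: list[int]
    mean_unique: list[float]
    sd_unique: list[float]
    reps: int
    seed: int


def rarefaction(
    assignments: Sequence[str],
    depths: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Mean unique features among ``d`` reads sampled without replacement.

    ``assignments`` maps each read to its feature (transcript or gene);
    pass the per-read transcript labels to rarefy transcript discovery.
    """
    labels = np.asarray(assignments)
    n = len(labels)
    for d in depths:
        if d > n:
            raise ValidationError(f"depth {d} exceeds total reads {n}")
    rng = np.random.default_rng(seed)
    codes = pd.factorize(labels)[0]
    means, sds = [], []
    for d in depths:
        uniques = np.empty(reps)
        for r in range(reps):
            take = rng.choice(n, size=d, replace=False)
            uniques[r] = len(np.unique(codes[take]))
        means.append(float(uniques.mean()))
        sds.append(float(uniques.std(ddof=1)) if reps > 1 else 0.0)
    return RarefactionCurve(list(depths), means, sds, reps, seed)


def rarefaction_expectation(
    feature_counts: Sequence[int], depth: int
) -> float:
    """Closed-form expected unique features at a subsampling depth:
    sum_i [1 - C(N - n_i, d) / C(N, d)] (hypergeometric)."""
    counts = np.asarray(feature_counts)
    total = int(counts.sum())
    p_missing = stats.hypergeom.pmf(0, total, counts, depth)
    return float(np.sum(1.0 - p_missing))


# ---------------------------------------------------------------------------
# DTE / DTU


@dataclass
class DteResult:
    transcript_id: str
    mean_a: float
    mean_b: float
    p_value: float
    direction: int  # +1: higher in A, -1: higher in B, 0: equal means


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value: exact when the pooled sample is small
    (n <= 20) and tie-free, mid-rank normal approximation with continuity
    correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    method = "exact" if exact else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def dte_wilcoxon(
    tpm: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-transcript two-sided Wilcoxon rank-sum DTE between two groups
    of samples (columns of the TPM matrix)."""
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    va = tpm[group_a].to_numpy(dtype=float)
    vb = tpm[group_b].to_numpy(dtype=float)
    rows = []
    for i, tid in enumerate(tpm.index):
        mean_a, mean_b = va[i].mean(), vb[i].mean()
        if np.all(va[i] == va[i][0]) and np.all(vb[i] == vb[i][0]) and va[i][0] == vb[i][0]:
            p = 1.0
        else:
            p = wilcoxon_rank_sum(va[i], vb[i])
        rows.append(
            {
                "transcript_id": tid,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "p_value": p,
                "direction": int(np.sign(mean_a - mean_b)),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


@dataclass
class DtuCall:
    gene_id: str
    transcripts: list[str]
    rule: str  # fetal_adult | region_pair
    details: dict = field(default_factory=dict)


def dtu_fetal_adult(
    dte: pd.DataFrame,
    transcript_gene: Mapping[str, str],
    alpha: float = DTE_ALPHA,
    min_delta_tpm: float = DTU_MIN_DELTA_TPM,
) -> list[DtuCall]:
    """Replicated-design DTU: a gene is called when two of its transcripts
    show opposite-direction significant DTE, each with |mean TPM
    difference| > ``min_delta_tpm``."""
    genes = pd.Series({t: transcript_gene.get(t) for t in dte.index})
    calls = []
    sig = dte[(dte["p_value"] < alpha)].copy()
    sig["delta"] = sig["mean_a"] - sig["mean_b"]
    sig = sig[sig["delta"].abs() > min_delta_tpm]
    for gene_id, idx in genes.groupby(genes).groups.items():
        g = sig.loc[sig.index.intersection(idx)]
        up = g[g["delta"] > 0]
        down = g[g["delta"] < 0]
        if len(up) and len(down):
            tids = list(up.index) + list(down.index)
            calls.append(
                DtuCall(
                    gene_id,
                    tids,
                    "fetal_adult",
                    {
                        "up_in_a": list(up.index),
                        "up_in_b": list(down.index),
                    },
                )
            )
    return sorted(calls, key=lambda c: c.gene_id)


def region_pair_flags(
    tpm: pd.DataFrame,
    region_a: Sequence[str],
    region_b: Sequence[str],
    min_fc: float = REGION_MIN_FOLD_CHANGE,
    min_delta: float = REGION_MIN_DELTA_TPM,
    pseudocount: float = REGION_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-transcript threshold flags for unreplicated region pairs:
    fold change (with pseudocount) >= min_fc in either direction and
    absolute mean difference > min_delta."""
    mean_a = tpm[list(region_a)].mean(axis=1)
    mean_b = tpm[list(region_b)].mean(axis=1)
    fc = (mean_a + pseudocount) / (mean_b + pseudocount)
    flagged = ((fc >= min_fc) | (fc <= 1.0 / min_fc)) & (
        (mean_a - mean_b).abs() > min_delta
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "delta": mean_a - mean_b,
            "flagged": flagged,
            "direction": np.sign(mean_a - mean_b).astype(int),
        }
    )


def dtu_region_pair(
    tpm: pd.DataFrame,
    transcript_gene: Mapping[str, str],
    region_a: Sequence[str],
    region_b: Sequence[str],
    min_fc: float = REGION_MIN_FOLD_CHANGE,
    min_delta: float = REGION_MIN_DELTA_TPM,
    pseudocount: float = REGION_PSEUDOCOUNT,
) -> tuple[pd.DataFrame, list[DtuCall]]:
    """Unreplicated-design DTU: gene-level call when >= 2 transcripts are
    flagged in opposite directions."""
    flags = region_pair_flags(tpm, region_a, region_b, min_fc, min_delta, pseudocount)
    genes = pd.Series({t: transcript_gene.get(t) for t in flags.index})
    calls = []
    hit = flags[flags["flagged"]]
    for gene_id, idx in genes.groupby(genes).groups.items():
        g = hit.loc[hit.index.intersection(idx)]
        up = g[g["direction"] > 0]
        down = g[g["direction"] < 0]
        if len(up) and len(down):
            calls.append(
                DtuCall(
                    gene_id,
                    list(up.index) + list(down.index),
                    "region_pair",
                )
            )
    return flags, sorted(calls, key=lambda c: c.gene_id)


def group_specific_transcripts(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    mode: str = "detection",
    tpm_min: float = 20.0,
    tpm: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Transcripts exclusive to one sample group.

    ``detection`` mode: count > 0 in every sample of one group and 0 in
    all samples of every other group.  ``tpm_threshold`` mode: group mean
    TPM > ``tpm_min`` in exactly one group.
    """
    if mode not in ("detection", "tpm_threshold"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, list[str]] = {g: [] for g in groups}
    if mode == "detection":
        for g, samples in groups.items():
            others = [
                s for g2, ss in groups.items() if g2 != g for s in ss
            ]
            mask = (counts[list(samples)] > 0).all(axis=1) & (
                counts[others] == 0
            ).all(axis=1)
            out[g] = list(counts.index[mask])
        return out
    if tpm is None:
        tpm = tpm_normalize(counts)
    means = pd.DataFrame(
        {g: tpm[list(ss)].mean(axis=1) for g, ss in groups.items()}
    )
    above = means > tpm_min
    for g in groups:
        mask = above[g] & ~above.drop(columns=g).any(axis=1)
        out[g] = list(means.index[mask])
    return out


def cross_dataset_compare(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    homolog_map: Mapping[str, str] | None = None,
) -> dict[str, object]:
    """Join per-gene isoform counts across two datasets and rank the most
    divergent genes.

    ``homolog_map`` maps dataset-B gene ids to dataset-A ids; non-unique
    target ids are dropped.  Relative difference is max(a, b) /
    max(min(a, b), 1); absolute difference is |a - b|.
    """
    sa = pd.Series(counts_a, dtype=float)
    sb = pd.Series(counts_b, dtype=float)
    if homolog_map is not None:
        hm = pd.Series(homolog_map)
        hm = hm[~hm.duplicated(keep=False)]  # one-to-one only
        sb = sb[sb.index.intersection(hm.index)]
        sb.index = hm.loc[sb.index]
    shared = sa.index.intersection(sb.index)
    if len(shared) == 0:
        raise ValidationError("no shared genes after homolog mapping")
    df = pd.DataFrame({"a": sa.loc[shared], "b": sb.loc[shared]})
    df["absolute_diff"] = (df["a"] - df["b"]).abs()
    df["relative_diff"] = df[["a", "b"]].max(axis=1) / df[["a", "b"]].min(
        axis=1
    ).clip(lower=1)
    corr = (
        float(stats.pearsonr(df["a"], df["b"])[0])
        if len(df) >= 3 and df["a"].nunique() > 1 and df["b"].nunique() > 1
        else None
    )
    return {
        "table": df,
        "n_shared": len(df),
        "correlation": corr,
        "top_absolute": df.sort_values("absolute_diff", ascending=False),
        "top_relative": df.sort_values("relative_diff", ascending=False),
    }
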