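"""Expression normalization, differential expression and the SDEG filter.

The study quantified expression as RPKM, called differential expression with
a negative-binomial model, and kept genes with |fold change| >= 2 at
FDR <= 0.05 as significantly differentially expressed genes (SDEGs).  This
module provides RPKM, median-of-ratios size factors, a negative-binomial
Wald test with moderated method-of-moments dispersion, Benjamini-Hochberg
FDR, the inclusive SDEG threshold filter, and the 2^-ddCt qPCR fold change.

The Wald test is a documented stand-in calibrated for direction and rough
error control at two replicates per group, not a re-implementation of any
particular DE engine; externally computed DEG tables are accepted through
:func:`trninfer.io.read_deg_table` so the network stages can also run on
statistics produced elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    Contrast,
    CountMatrix,
    PipelineParams,
    SDEGSet,
    ValidationError,
)

#: dispersion floor of the method-of-moments estimator
DISPERSION_FLOOR = 0.01
#: pseudocount (normalized counts) stabilizing fold changes at zero means
PSEUDOCOUNT = 0.5
#: weight of the genewise dispersion estimate against the trend; with two
#: replicates the genewise estimate carries one degree of freedom, so most
#: of the weight goes to the trend
GENE_DISPERSION_WEIGHT = 0.3


def rpkm(counts: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    value(g, s) = count(g, s) / (length_bp(g)/1000) / (colsum(s)/1e6).
    Zero counts map to exactly zero RPKM.
    """
    colsums = counts.counts.sum(axis=0, dtype="int64")
    if (colsums == 0).any():
        empty = [counts.sample_ids[j] for j in np.flatnonzero(colsums == 0)]
        raise ValidationError(f"empty library (zero column sum): {empty}")
    lengths_kb = np.array([g.length_bp for g in counts.genes], dtype=float) / 1000.0
    values = counts.counts / lengths_kb[:, None] / (colsums[None, :] / 1e6)
    return pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids)


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    For each gene with positive counts in every sample, the ratio of each
    sample's count to the gene's geometric mean is taken; a sample's factor
    is the median ratio.  Identical columns yield factors of exactly 1.
    """
    mat = counts.counts.astype(float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValidationError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    sub = mat[all_positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    return np.median(ratios, axis=0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("bh_adjust requires a non-empty list")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _group_columns(counts: CountMatrix, genotype: str, temperature_c: float) -> list[int]:
    cols = counts.columns_for(genotype, temperature_c)
    if not cols:
        raise ValidationError(
            f"no samples for genotype {genotype!r} at {temperature_c:g} degC"
        )
    if len(cols) < 2:
        raise ValidationError(
            f"genotype {genotype!r} at {temperature_c:g} degC has {len(cols)} "
            "replicate(s); >= 2 required"
        )
    return cols


def _moment_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Moderated method-of-moments NB dispersion, one value per gene.

    phi solves var = mu + phi mu^2 within each group.  With two replicates
    the per-gene estimate has a single degree of freedom, so it is averaged
    with the genewise mean dispersion of similarly expressed genes (upper
    and lower expression halves) before flooring — small-sample moderation
    in the spirit of shrinking toward a dispersion trend.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cols in groups:
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num[ok] += var[ok] - mu[ok]
        den[ok] += mu[ok] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_gene = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    phi_gene = np.clip(phi_gene, 0.0, None)

    overall_mu = norm.mean(axis=1)
    expressed = overall_mu > 0
    phi = np.full(norm.shape[0], DISPERSION_FLOOR)
    if expressed.any():
        median_mu = np.median(overall_mu[expressed])
        trend = np.empty(norm.shape[0])
        for mask in (expressed & (overall_mu <= median_mu),
                     expressed & (overall_mu > median_mu)):
            if mask.any():
                trend[mask] = phi_gene[mask].mean()
        w = GENE_DISPERSION_WEIGHT
        phi[expressed] = w * phi_gene[expressed] + (1 - w) * trend[expressed]
    return np.maximum(phi, DISPERSION_FLOOR)


def de_test(counts: CountMatrix, contrast: Contrast) -> pd.DataFrame:
    """Negative-binomial Wald differential-expression test for one contrast.

    Counts are normalized by median-of-ratios size factors; per gene the
    log2 fold change log2((mean_test + c) / (mean_ref + c)) with pseudocount
    c = 0.5 is tested with a Wald z computed under the NB variance
    mu + phi mu^2 (delta method on the log2 scale).  Genes with zero counts
    throughout are flagged untestable with p = 1.

    Returns a DataFrame indexed by gene_id with columns log2_fc, p_raw,
    q_fdr, mean_ref, mean_test, untestable.
    """
    ref_cols = _group_columns(counts, contrast.reference_genotype, contrast.temperature_c)
    test_cols = _group_columns(counts, contrast.deletion_genotype, contrast.temperature_c)
    used = ref_cols + test_cols

    sub = CountMatrix(
        genes=counts.genes,
        samples=[counts.samples[j] for j in used],
        counts=counts.counts[:, used],
    )
    norm = sub.counts / size_factors(sub)[None, :]
    ref_idx = list(range(len(ref_cols)))
    test_idx = list(range(len(ref_cols), len(used)))

    mean_ref = norm[:, ref_idx].mean(axis=1)
    mean_test = norm[:, test_idx].mean(axis=1)
    c = PSEUDOCOUNT
    log2_fc = np.log2(mean_test + c) - np.log2(mean_ref + c)

    phi = _moment_dispersion(norm, [np.array(ref_idx), np.array(test_idx)])

    def var_log2_mean(mean: np.ndarray, n: int) -> np.ndarray:
        mu = mean + c  # floor keeps the variance positive at zero means
        var_mean = (mu + phi * mu**2) / n
        return var_mean / (mu * np.log(2.0)) ** 2

    se = np.sqrt(
        var_log2_mean(mean_ref, len(ref_idx)) + var_log2_mean(mean_test, len(test_idx))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2_fc / np.maximum(se, 1e-300), 0.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))

    untestable = (mean_ref == 0) & (mean_test == 0)
    log2_fc[untestable] = 0.0
    p_raw[untestable] = 1.0
    p_raw = np.clip(p_raw, 0.0, 1.0)

    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_raw": p_raw,
            "q_fdr": bh_adjust(p_raw),
            "mean_ref": mean_ref,
            "mean_test": mean_test,
            "untestable": untestable,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )


def sdeg_filter(table: pd.DataFrame, contrast: Contrast,
                params: PipelineParams | None = None) -> SDEGSet:
    """Apply the SDEG thresholds: |fold change| >= fc_threshold and FDR <= alpha.

    Both boundaries are inclusive ("2.0 or greater", "0.05 or less"), so a
    gene at exactly log2_fc = 1 and q = 0.05 is kept.
    """
    params = params or PipelineParams()
    lfc_cut = np.log2(params.fc_threshold)
    sig = table["q_fdr"] <= params.fdr_alpha
    up = set(table.index[sig & (table["log2_fc"] >= lfc_cut)])
    down = set(table.index[sig & (table["log2_fc"] <= -lfc_cut)])
    return SDEGSet(contrast=contrast, up=up, down=down)


@dataclass(frozen=True)
class QPCRMeasurement:
    """Cycle thresholds for target and reference genes in test and control."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for name in ("ct_target_test", "ct_ref_test", "ct_target_control", "ct_ref_control"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


def ddct_fold_change(m: QPCRMeasurement) -> float:
    """Signed relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,control - Ct_ref,control);
    the raw ratio r = 2^-ddCt is reported as r when r >= 1 and as -1/r
    otherwise, the signed convention used when fold changes are quoted as
    e.g. "4.3 and -1.1".
    """
    ddct = (m.ct_target_test - m.ct_ref_test) - (m.ct_target_control - m.ct_ref_control)
    ratio = 2.0 ** (-ddct)
    return ratio if ratio >= 1.0 else -1.0 / ratio
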