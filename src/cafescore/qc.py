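"""Variant- and sample-level genotype quality control.

Implements the exact Hardy-Weinberg test on hard-called genotypes, the
variant filters (HWE, MAF, call rate, imputation quality), the sample filters
(call rate, heterozygosity fence), a method-of-moments pi-hat relatedness
estimator, greedy relatedness pruning, and ancestry principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import QcThresholds
from .genotypes import GenotypeMatrix


@dataclass
class QcReport:
    """Bookkeeping for exclusions: every excluded record carries >=1 reason."""

    variants_excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reasons"]))
    samples_excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "reasons"]))
    relatedness_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_a", "sample_b", "pihat"]))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg P value for one genotype table.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (the classical exact test, not mid-P).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_aa + n_Aa  # minor-ish allele count; symmetry makes choice immaterial
    # attainable heterozygote counts share the parity of n_a
    het = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    hom_a = (n_a - het) // 2
    hom_A = n - het - hom_a
    logp = (gammaln(n + 1) - gammaln(hom_A + 1) - gammaln(het + 1)
            - gammaln(hom_a + 1) + het * np.log(2.0))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(het, n_Aa)]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _hard_genotype_counts(genotypes: GenotypeMatrix):
    """Per-variant (n_hom_other, n_het, n_hom_counted) from hard calls."""
    hard = genotypes.hard_calls()
    n0 = np.nansum(hard == 0, axis=0)
    n1 = np.nansum(hard == 1, axis=0)
    n2 = np.nansum(hard == 2, axis=0)
    return n0.astype(int), n1.astype(int), n2.astype(int)


def variant_qc(genotypes: GenotypeMatrix, thr: QcThresholds):
    """Apply the variant filters; returns (keep mask, QcReport).

    A variant is kept iff HWE exact P >= ``hwe_p_min``, MAF >= ``maf_min``,
    call rate >= ``variant_call_min``, and imputation quality >=
    ``impq_min``.  HWE is computed on hard-called genotypes.
    """
    if genotypes.n_variants == 0 or genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    dos = genotypes.dosage
    call_rate = 1.0 - np.isnan(dos).mean(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dos, axis=0) / 2.0
    f = np.where(np.isnan(f), 0.0, f)
    maf = np.minimum(f, 1.0 - f)
    n0, n1, n2 = _hard_genotype_counts(genotypes)
    hwe_p = np.ones(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        if n0[j] + n1[j] + n2[j] > 0:
            hwe_p[j] = hwe_exact_test(n0[j], n1[j], n2[j])
    impq = genotypes.variants["impq"].to_numpy(float)

    fails = {
        "hwe": hwe_p < thr.hwe_p_min,
        "maf": maf < thr.maf_min,
        "call_rate": call_rate < thr.variant_call_min,
        "impq": impq < thr.impq_min,
    }
    keep = ~np.logical_or.reduce(list(fails.values()))
    report = QcReport()
    excluded = np.flatnonzero(~keep)
    if len(excluded):
        reasons = [";".join(name for name, mask in fails.items() if mask[j])
                   for j in excluded]
        report.variants_excluded = pd.DataFrame({
            "id": genotypes.variants.loc[excluded, "id"].to_numpy(),
            "reasons": reasons})
    return keep, report


def sample_qc(genotypes: GenotypeMatrix, thr: QcThresholds):
    """Apply the sample filters; returns (keep mask, QcReport).

    A sample is kept iff its call rate >= ``sample_call_min`` and its
    heterozygosity rate (hard-called heterozygotes over non-missing calls) is
    at most ``median + het_iqr_mult * IQR``, median and IQR taken over the
    samples passing the call-rate filter.  The fence is one-sided high.
    """
    if genotypes.n_samples < 2:
        raise ValueError("sample QC requires at least 2 samples")
    dos = genotypes.dosage
    call_rate = 1.0 - np.isnan(dos).mean(axis=1)
    hard = genotypes.hard_calls()
    n_called = (~np.isnan(hard)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        het = np.nansum(hard == 1, axis=1) / np.maximum(n_called, 1)
    pass_cr = call_rate >= thr.sample_call_min
    ref = het[pass_cr] if pass_cr.any() else het
    med = np.median(ref)
    iqr = np.percentile(ref, 75) - np.percentile(ref, 25)
    fence = med + thr.het_iqr_mult * iqr
    fails = {"call_rate": ~pass_cr, "heterozygosity": het > fence + 1e-12}
    keep = ~(fails["call_rate"] | fails["heterozygosity"])
    report = QcReport()
    excluded = np.flatnonzero(~keep)
    if len(excluded):
        reasons = [";".join(name for name, mask in fails.items() if mask[i])
                   for i in excluded]
        report.samples_excluded = pd.DataFrame({
            "id": np.asarray(genotypes.samples)[excluded], "reasons": reasons})
    return keep, report


def estimate_pihat(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments IBD estimate for every sample pair.

    From identity-by-state counts and population allele frequencies, solves
    for P(IBD=0/1/2) and returns pi-hat = P(IBD=1)/2 + P(IBD=2) truncated to
    [0, 1].  Columns: sample_a, sample_b, pihat.
    """
    if genotypes.n_samples < 2:
        raise ValueError("pi-hat requires at least 2 samples")
    if genotypes.n_variants < 50:
        raise ValueError("pi-hat requires at least 50 variants")
    hard = genotypes.hard_calls()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(hard, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("all variants are monomorphic; pi-hat undefined")
    hard = hard[:, poly]
    p = p[poly]
    q = 1.0 - p
    m = hard.shape[1]

    # per-locus IBS expectations, averaged over loci
    e_ibs0_ibd0 = np.mean(2 * p ** 2 * q ** 2)
    e_ibs1_ibd0 = np.mean(4 * p ** 3 * q + 4 * p * q ** 3)
    e_ibs2_ibd0 = np.mean(p ** 4 + q ** 4 + 4 * p ** 2 * q ** 2)
    e_ibs1_ibd1 = np.mean(2 * p ** 2 * q + 2 * p * q ** 2)
    e_ibs2_ibd1 = np.mean(p ** 3 + q ** 3 + p * q)

    obs = ~np.isnan(hard)
    g = np.where(obs, hard, 0.0)
    a0 = ((g == 0) & obs).astype(float)
    a1 = ((g == 1) & obs).astype(float)
    a2 = ((g == 2) & obs).astype(float)
    valid = obs.astype(float) @ obs.astype(float).T
    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    ibs1 = valid - ibs0 - ibs2

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = ibs0 / (e_ibs0_ibd0 * valid)
        p1 = (ibs1 - p0 * e_ibs1_ibd0 * valid) / (e_ibs1_ibd1 * valid)
        p2 = (ibs2 - p0 * e_ibs2_ibd0 * valid - p1 * e_ibs2_ibd1 * valid) / valid
    p0 = np.clip(p0, 0.0, 1.0)
    p1 = np.clip(p1, 0.0, 1.0)
    p2 = np.clip(p2, 0.0, 1.0)
    pihat = np.clip(p1 / 2.0 + p2, 0.0, 1.0)

    samples = np.asarray(genotypes.samples)
    ia, ib = np.triu_indices(len(samples), k=1)
    return pd.DataFrame({"sample_a": samples[ia], "sample_b": samples[ib],
                         "pihat": pihat[ia, ib]})


def prune_related(pairs: pd.DataFrame, thr: QcThresholds) -> list:
    """Samples to drop so no pair with pi-hat > ``pihat_max`` remains.

    Greedy: within the related graph, repeatedly drop the sample with the
    most related partners (ties broken by lexicographically smallest ID)
    until no edge remains.  Returns the sorted list of dropped sample IDs.
    """
    edges = pairs.loc[pairs["pihat"] > thr.pihat_max, ["sample_a", "sample_b"]]
    adj: dict = {}
    for a, b in edges.itertuples(index=False):
        a, b = str(a), str(b)
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    dropped = []
    while any(adj.values()):
        victim = min(adj, key=lambda s: (-len(adj[s]), s))
        dropped.append(victim)
        for other in adj.pop(victim):
            adj[other].discard(victim)
        adj = {s: nb for s, nb in adj.items() if nb}
    return sorted(dropped)


def ancestry_pcs(genotypes: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k principal components of the column-standardized dosage matrix.

    Stands in for reference-panel ancestry projection: PCA on the analysis
    sample itself.  Components are orthogonal and deterministic up to sign;
    the sign is fixed so each component's largest-magnitude variant loading
    is positive.  ``k = 0`` returns an empty table.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    samples = [str(s) for s in genotypes.samples]
    if k == 0:
        return pd.DataFrame(index=pd.Index(samples, name="participant_id"))
    dos = genotypes.dosage
    if k > min(dos.shape):
        raise ValueError(f"k={k} exceeds matrix dimensions {dos.shape}")
    col_mean = np.nanmean(dos, axis=0)
    filled = np.where(np.isnan(dos), col_mean, dos)
    sd = filled.std(axis=0)
    if (sd == 0).any():
        sd = np.where(sd == 0, 1.0, sd)
    x = (filled - col_mean) / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[k - 1] <= max(x.shape) * np.finfo(float).eps * s[0]:
        raise ValueError(f"k={k} exceeds the rank of the genotype matrix")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)],
                        index=pd.Index(samples, name="participant_id"))


def run_qc(genotypes: GenotypeMatrix, thr: QcThresholds, n_pcs: int = 5):
    """Full QC stage: variant filters, sample filters, relatedness pruning, PCs.

    Returns (filtered GenotypeMatrix, pcs DataFrame, QcReport).
    """
    vmask, vreport = variant_qc(genotypes, thr)
    gm = genotypes.subset(variant_mask=vmask)
    smask, sreport = sample_qc(gm, thr)
    gm = gm.subset(sample_mask=smask)
    pairs = estimate_pihat(gm) if gm.n_variants >= 50 and gm.n_samples >= 2 \
        else pd.DataFrame(columns=["sample_a", "sample_b", "pihat"])
    drop = set(prune_related(pairs, thr))
    if drop:
        keep = np.array([s not in drop for s in gm.samples])
        gm = gm.subset(sample_mask=keep)
        rel = pd.DataFrame({"id": sorted(drop),
                            "reasons": ["relatedness"] * len(drop)})
        sreport.samples_excluded = pd.concat(
            [sreport.samples_excluded, rel], ignore_index=True)
    report = QcReport(variants_excluded=vreport.variants_excluded,
                      samples_excluded=sreport.samples_excluded,
                      relatedness_pairs=pairs.loc[pairs["pihat"] > thr.pihat_max]
                      .reset_index(drop=True))
    pcs = ancestry_pcs(gm, min(n_pcs, max(gm.n_samples - 1, 0), gm.n_variants))
    return gm, pcs, report
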