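"""Polygenic score construction.

Two families of scores:

* fixed-loci PRS: the published BMI loci (97 = 54 CNS + 43 non-CNS) weighted
  by their discovery effect sizes and rescaled to a risk-allele-count scale;
* genome-wide polygenic score (GPS): greedy LD clumping (most significant
  variant kept within a 250 kb window, correlated neighbours with r² above
  0.1 removed) followed by a discovery-P-value threshold, with the best-fit
  threshold chosen by the variance it explains in inverse-normalized BMI.

All scores count effect alleles on the risk orientation: any variant whose
discovery β is negative is flipped (allele swap + sign flip) before summing,
so every weight is non-negative and the raw score is a weighted count of
BMI-increasing alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GpsConfig
from .genotypes import GenotypeMatrix

WEIGHT_COLUMNS = ["ID", "CHR", "POS", "EA", "OA", "BETA", "P"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ScoreSet:
    """Per-participant scores for one score definition.

    ``raw`` is the β-weighted risk-allele sum, ``scaled`` the
    risk-allele-count rescaling (in [0, 2M]), ``standardized`` mean-0/SD-1,
    and ``quartile`` the population-distribution quartile (1 = lowest risk).
    """

    name: str
    samples: list
    raw: np.ndarray
    scaled: np.ndarray
    standardized: np.ndarray
    quartile: np.ndarray
    n_variants: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.samples, "score_name": self.name,
            "raw": self.raw, "scaled": self.scaled,
            "standardized": self.standardized, "quartile": self.quartile,
        })


def read_weights(path) -> pd.DataFrame:
    """Read a tab-delimited weight table (ID/CHR/POS/EA/OA/BETA/P[/CNS])."""
    df = pd.read_csv(path, sep="\t")
    return validate_weights(df)


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if not weights["ID"].is_unique:
        raise ValueError("weight table variant IDs must be unique")
    if not np.isfinite(weights["BETA"]).all():
        raise ValueError("weight table contains non-finite BETA")
    p = weights["P"].to_numpy(float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("weight table P values must lie in (0, 1]")
    if "CNS" not in weights.columns:
        weights = weights.assign(CNS="unannotated")
    return weights.reset_index(drop=True)


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosages_a, float)
    b = np.asarray(dosages_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("dosage vectors must be 1-D, equal length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("LD r² undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def clump(weights: pd.DataFrame, genotypes: GenotypeMatrix,
          cfg: GpsConfig) -> list:
    """Greedy P-value-ordered LD clumping.

    Repeatedly retains the unretired variant with the smallest discovery P
    (ties: smaller position, then lexicographically smaller ID) and retires
    all unretired variants on the same chromosome within ±``clump_window``
    whose in-sample r² with it exceeds ``clump_r2``.  Returns retained
    variant IDs sorted by chromosome then position.
    """
    weights = validate_weights(weights)
    vindex = {vid: j for j, vid in enumerate(genotypes.variants["id"])}
    missing = [vid for vid in weights["ID"] if vid not in vindex]
    if missing:
        raise ValueError(f"weight variants absent from genotypes: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    w = weights.sort_values(["P", "POS", "ID"], kind="mergesort").reset_index(drop=True)
    chrom = w["CHR"].astype(str).to_numpy()
    pos = w["POS"].to_numpy(int)
    ids = w["ID"].to_numpy()
    cols = np.array([vindex[v] for v in ids])
    col_mean = np.nanmean(genotypes.dosage, axis=0)
    dos = np.where(np.isnan(genotypes.dosage), col_mean, genotypes.dosage)

    active = np.ones(len(w), bool)
    retained = []
    for i in range(len(w)):
        if not active[i]:
            continue
        active[i] = False
        retained.append(i)
        near = np.flatnonzero(active & (chrom == chrom[i])
                              & (np.abs(pos - pos[i]) <= cfg.clump_window))
        if len(near) == 0:
            continue
        x = dos[:, cols[i]]
        if np.ptp(x) == 0:
            continue
        xc = x - x.mean()
        denom_x = (xc ** 2).sum()
        y = dos[:, cols[near]]
        yc = y - y.mean(axis=0)
        denom_y = (yc ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = (xc @ yc) ** 2 / (denom_x * denom_y)
        r2 = np.where(denom_y == 0, 0.0, r2)
        active[near[r2 > cfg.clump_r2]] = False

    kept = w.loc[retained, ["ID", "CHR", "POS"]]
    kept = kept.sort_values(["CHR", "POS"], kind="mergesort")
    return kept["ID"].tolist()


def _orient(weights: pd.DataFrame, genotypes: GenotypeMatrix):
    """Resolve effect-allele orientation; returns (dosage of risk allele, |β|).

    Dosages count the weight table's effect allele (allele swap and strand
    complement resolved against the genotype metadata); variants with
    negative β are then flipped to the risk orientation so every returned
    weight is non-negative.  Missing dosages are imputed as 2 × effect-allele
    frequency.
    """
    vmeta = genotypes.variants.set_index("id")
    cols, flips = [], []
    for vid, ea, oa in weights[["ID", "EA", "OA"]].itertuples(index=False):
        if vid not in vmeta.index:
            raise ValueError(f"weight variant '{vid}' absent from genotypes")
        a1, a0 = str(vmeta.at[vid, "a1"]), str(vmeta.at[vid, "a0"])
        ea, oa = str(ea), str(oa)
        cea = "".join(_COMPLEMENT.get(b, b) for b in ea)
        coa = "".join(_COMPLEMENT.get(b, b) for b in oa)
        if (ea, oa) == (a1, a0) or (cea, coa) == (a1, a0):
            flip = False
        elif (ea, oa) == (a0, a1) or (cea, coa) == (a0, a1):
            flip = True
        else:
            raise ValueError(
                f"allele mismatch for '{vid}': weights {ea}/{oa} vs genotypes {a1}/{a0}")
        cols.append(vmeta.index.get_loc(vid))
        flips.append(flip)
    idx = np.asarray(cols)
    dos = genotypes.dosage[:, idx].copy()
    freq = genotypes.variants["freq"].to_numpy(float)[idx]
    fill = np.where(np.asarray(flips), 2 * (1 - freq), 2 * freq)
    dos = np.where(np.asarray(flips), 2.0 - dos, dos)
    dos = np.where(np.isnan(dos), fill, dos)
    beta = weights["BETA"].to_numpy(float).copy()
    neg = beta < 0
    dos[:, neg] = 2.0 - dos[:, neg]
    return dos, np.abs(beta)


def raw_score(weights: pd.DataFrame, genotypes: GenotypeMatrix) -> np.ndarray:
    """β-weighted risk-allele sum per participant (orientation-resolved)."""
    weights = validate_weights(weights)
    dos, beta = _orient(weights, genotypes)
    return dos @ beta


def scale_prs(raw: np.ndarray, weights: pd.DataFrame) -> np.ndarray:
    """Rescale a raw PRS to the risk-allele-count scale.

    scaled = raw × 2M / (2 Σβ) with M the variant count and β the
    risk-oriented (non-negative) weights; the result lies in [0, 2M] and is
    interpretable as a weighted count of risk alleles, so downstream effects
    read as per-1-risk-allele increases.
    """
    beta_sum = float(np.abs(weights["BETA"].to_numpy(float)).sum())
    if beta_sum <= 0:
        raise ValueError("sum of effect sizes must be positive for PRS scaling")
    m = len(weights)
    return np.asarray(raw, float) * (2.0 * m) / (2.0 * beta_sum)


def assign_quartiles(values) -> np.ndarray:
    """Population-distribution quartiles, 1 (lowest) .. 4 (highest).

    Cut points at the empirical 25th/50th/75th percentiles; values tied with
    a boundary go to the lower quartile.
    """
    x = np.asarray(values, float)
    if len(x) < 4:
        raise ValueError("quartile assignment requires n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("quartiles undefined for a constant score")
    cuts = np.percentile(x, [25, 50, 75])
    q = 1 + (x > cuts[0]).astype(int) + (x > cuts[1]) + (x > cuts[2])
    return q


def make_score_set(name: str, weights: pd.DataFrame,
                   genotypes: GenotypeMatrix) -> ScoreSet:
    """Raw, scaled, standardized scores and quartiles for one weight table."""
    weights = validate_weights(weights)
    raw = raw_score(weights, genotypes)
    scaled = scale_prs(raw, weights)
    sd = raw.std()
    if sd == 0:
        raise ValueError(f"score '{name}' is constant; cannot standardize")
    standardized = (raw - raw.mean()) / sd
    return ScoreSet(name=name, samples=list(genotypes.samples), raw=raw,
                    scaled=scaled, standardized=standardized,
                    quartile=assign_quartiles(raw), n_variants=len(weights))


def partition_scores(weights: pd.DataFrame, genotypes: GenotypeMatrix,
                     names=("BMI_97", "BMI_CNS", "BMI_nonCNS")):
    """Full, CNS, and non-CNS score sets from one annotated weight table.

    Every variant must carry a CNS or non-CNS flag; the two sub-scores are
    computed on the disjoint subsets and their raw scores sum to the full
    raw score.
    """
    weights = validate_weights(weights)
    flags = weights["CNS"].astype(str)
    bad = ~flags.isin(["CNS", "non-CNS"])
    if bad.any():
        raise ValueError("unannotated variant(s) in fixed-loci weight table: "
                         f"{weights.loc[bad, 'ID'].tolist()[:5]}")
    cns = weights[flags == "CNS"]
    noncns = weights[flags == "non-CNS"]
    if len(cns) == 0 or len(noncns) == 0:
        raise ValueError("both CNS and non-CNS subsets must be non-empty")
    return (make_score_set(names[0], weights, genotypes),
            make_score_set(names[1], cns, genotypes),
            make_score_set(names[2], noncns, genotypes))


def filter_gps_weights(weights: pd.DataFrame, genotypes: GenotypeMatrix,
                       cfg: GpsConfig) -> pd.DataFrame:
    """Restrict a genome-wide weight table to MAF > maf_min and impq >= impq_min."""
    weights = validate_weights(weights)
    vmeta = genotypes.variants.set_index("id")
    keep = []
    for vid in weights["ID"]:
        if vid not in vmeta.index:
            keep.append(False)
            continue
        f = float(vmeta.at[vid, "freq"])
        keep.append(min(f, 1 - f) > cfg.maf_min
                    and float(vmeta.at[vid, "impq"]) >= cfg.impq_min)
    return weights.loc[np.asarray(keep)].reset_index(drop=True)


def build_gps(weights: pd.DataFrame, genotypes: GenotypeMatrix,
              threshold: float, cfg: GpsConfig,
              clumped_ids: list | None = None,
              name: str = "BMI_GPS") -> ScoreSet:
    """Genome-wide score at one discovery-P threshold.

    Clumps (unless pre-clumped IDs are supplied — clumping does not depend on
    the threshold), keeps retained variants with P <= threshold, and scores.
    """
    weights = validate_weights(weights)
    if clumped_ids is None:
        clumped_ids = clump(weights, genotypes, cfg)
    sub = weights[weights["ID"].isin(clumped_ids) & (weights["P"] <= threshold)]
    if len(sub) == 0:
        raise ValueError(f"no variants survive P threshold {threshold}")
    return make_score_set(name, sub.reset_index(drop=True), genotypes)


def best_fit_threshold(weights: pd.DataFrame, genotypes: GenotypeMatrix,
                       bmi, cfg: GpsConfig, covariates: pd.DataFrame | None = None):
    """Threshold scan with best-fit selection on inverse-normalized BMI.

    For each threshold in ``cfg.thresholds``, regresses the cohort's
    inverse-normalized BMI on the standardized score (plus optional covariate
    columns) and selects the threshold with the largest model R² (ties: the
    smaller threshold).  Returns (threshold, ScoreSet, r2_by_threshold dict).
    """
    from .association import inverse_normal_transform

    if len(cfg.thresholds) < 1:
        raise ValueError("threshold grid must be non-empty")
    bmi = np.asarray(bmi, float)
    if np.ptp(bmi) == 0:
        raise ValueError("BMI is constant; best-fit selection undefined")
    y = inverse_normal_transform(bmi)
    xcov = covariates.to_numpy(float) if covariates is not None else \
        np.empty((len(bmi), 0))
    clumped = clump(weights, genotypes, cfg)
    r2_by_threshold, sets = {}, {}
    for t in cfg.thresholds:
        try:
            ss = build_gps(weights, genotypes, t, cfg, clumped_ids=clumped)
        except ValueError:
            continue
        design = np.column_stack([np.ones(len(y)), ss.standardized, xcov])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        tss = ((y - y.mean()) ** 2).sum()
        r2_by_threshold[t] = float(1.0 - (resid ** 2).sum() / tss)
        sets[t] = ss
    if not r2_by_threshold:
        raise ValueError("no threshold in the grid retains any variant")
    best = max(sorted(r2_by_threshold), key=lambda t: r2_by_threshold[t])
    return best, sets[best], r2_by_threshold
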