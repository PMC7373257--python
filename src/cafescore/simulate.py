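"""Synthetic cohort generator.

Emulates the five inputs of the analysis — genotype dosages, a discovery-GWAS
weight table, a cafeteria transaction log, a meal-habits survey, and a
covariate table — from known generative parameters, so every downstream stage
can be tested against ground truth.

Generative model
----------------
* Genotypes: haplotypes in LD blocks via a first-order Markov copy mechanism;
  within a block all variants share one minor-allele frequency and adjacent
  variants have expected r² equal to ``block_r2``; blocks are separated by
  more than the clumping window so LD never crosses blocks.
* Liability: a standardized score ``z`` from sparse causal per-allele effects
  (at most one causal variant per LD block, mimicking independent GWAS loci).
* Weight table: causal effects perturbed by discovery-GWAS sampling noise at
  ``discovery_n``; two-sided normal P values; causal variants carry a CNS /
  non-CNS annotation, null variants are unannotated.
* BMI: linear in ``z`` with variance share ``bmi_h2`` of the non-demographic
  variance, plus small age and sex effects and Gaussian noise.
* Purchases: per-participant negative-binomial item counts over the 91-day
  (13-week) baseline window on weekdays within cafeteria hours; traffic-light
  colors from an exponentially tilted multinomial so that the expected Healthy
  Purchasing Score shifts by the configured percentage points per SD of ``z``;
  breakfast/lunch purchase times normal around means shifted by the timing
  effects.
* Survey: six binary behaviours from logistic models in ``z``, rendered as the
  five-category frequency strings the survey instrument uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .config import SimulationConfig
from .genotypes import GenotypeMatrix

CAFETERIA_OPEN, CAFETERIA_CLOSE = 360, 1200  # 06:00-20:00, minutes since midnight
BASELINE_DAYS = 91  # 13 whole weeks -> exactly 65 weekdays for any enrollment date

SKIP_COLS = ["skip_breakfast", "skip_lunch", "skip_dinner"]
HOME_COLS = ["home_breakfast", "home_lunch", "home_dinner"]

# Mean gap between top- and bottom-quartile conditional means of a standard
# normal: 2 * phi(Phi^-1(0.75)) / 0.25.
NORMAL_Q4_Q1_GAP = 2 * norm.pdf(norm.ppf(0.75)) / 0.25


@dataclass
class GroundTruth:
    """Generative quantities stored alongside a simulated dataset.

    Never consumed by the analysis pipeline itself; used only to check
    parameter recovery.
    """

    causal_betas: np.ndarray          # per-variant true per-allele effect
    true_score: np.ndarray            # per-participant standardized liability
    true_effects: dict = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    truth: GroundTruth
    weights: pd.DataFrame
    covariates: pd.DataFrame
    transactions: pd.DataFrame
    survey: pd.DataFrame


def _rngs(config: SimulationConfig, n_children: int = 3):
    """Independent deterministic generators for the simulation stages."""
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_children)]


def simulate_genotypes(config: SimulationConfig):
    """Simulate dosage genotypes in LD blocks plus the causal ground truth.

    Returns
    -------
    (GenotypeMatrix, GroundTruth)
    """
    rng, _, _ = _rngs(config)
    n, m, n_blocks = config.n_participants, config.n_variants, config.n_blocks
    bs = m // n_blocks
    block_maf = rng.uniform(config.maf_range[0], config.maf_range[1], n_blocks)
    maf = np.repeat(block_maf, bs)
    copy_p = np.sqrt(config.block_r2)

    dosage = np.zeros((n, m))
    for _hap in range(2):
        fresh = (rng.random((n, m)) < maf).astype(np.int8)
        copy = rng.random((n, m)) < copy_p
        copy[:, ::bs] = False  # block starts are always fresh draws
        h = np.empty((n, m), np.int8)
        h[:, 0] = fresh[:, 0]
        for j in range(1, m):
            h[:, j] = np.where(copy[:, j], h[:, j - 1], fresh[:, j])
        dosage += h
    dosage = dosage.astype(float)

    if config.missing_rate > 0:
        dosage[rng.random((n, m)) < config.missing_rate] = np.nan

    # Block layout: cycle chromosomes 1..22, >250 kb between blocks.
    chroms = np.empty(m, int)
    pos = np.empty(m, int)
    cursor = {}
    spacing, gap = 2_000, 500_000
    for b in range(n_blocks):
        chrom = (b % 22) + 1
        start = cursor.get(chrom, 1_000_000)
        idx = np.arange(b * bs, (b + 1) * bs)
        chroms[idx] = chrom
        pos[idx] = start + spacing * np.arange(bs)
        cursor[chrom] = start + spacing * bs + gap

    bases = np.array(list("ACGT"))
    a0_idx = rng.integers(0, 4, m)
    a1_idx = (a0_idx + rng.integers(1, 4, m)) % 4
    impq = rng.uniform(0.55, 1.0, m)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    freq = np.where(np.isnan(freq), maf, freq)

    variants = pd.DataFrame({
        "id": [f"snp{j + 1:05d}" for j in range(m)],
        "chrom": chroms, "pos": pos,
        "a1": bases[a1_idx], "a0": bases[a0_idx],
        "freq": freq, "impq": impq,
    })
    gm = GenotypeMatrix(samples=[f"P{i + 1:04d}" for i in range(n)],
                        variants=variants, dosage=dosage)

    # Causal architecture: at most one causal variant per block when possible.
    betas = np.zeros(m)
    n_causal = int(round(config.frac_causal * m))
    if n_causal > 0 and config.effect_sd > 0:
        if n_causal <= n_blocks:
            blocks = rng.choice(n_blocks, n_causal, replace=False)
            causal_idx = blocks * bs + rng.integers(0, bs, n_causal)
        else:
            causal_idx = rng.choice(m, n_causal, replace=False)
        betas[np.sort(causal_idx)] = rng.normal(0.0, config.effect_sd, n_causal)

    filled = np.where(np.isnan(dosage), 2 * freq, dosage)
    raw = filled @ betas
    sd = raw.std()
    true_score = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    truth = GroundTruth(causal_betas=betas, true_score=true_score)
    return gm, truth


def simulate_weights(genotypes: GenotypeMatrix, truth: GroundTruth,
                     config: SimulationConfig) -> pd.DataFrame:
    """Emulate a discovery-GWAS weight table for every simulated variant.

    Effect estimates are the true per-allele effects plus sampling noise with
    standard error 1/sqrt(2 p (1-p) N_discovery); P values are the matching
    two-sided normal tails.  Causal variants are annotated CNS or non-CNS
    (roughly 54:43, the published split of the 97 BMI loci); null variants are
    left unannotated.
    """
    _, rng, _ = _rngs(config)
    v = genotypes.variants
    p = np.clip(v["freq"].to_numpy(), 1e-4, 1 - 1e-4)
    se = 1.0 / np.sqrt(2 * p * (1 - p) * config.discovery_n)
    beta_hat = truth.causal_betas + rng.normal(0.0, se)
    pvals = np.clip(2 * norm.sf(np.abs(beta_hat) / se), 1e-300, 1.0)
    cns = np.where(truth.causal_betas != 0,
                   np.where(rng.random(len(v)) < 54 / 97, "CNS", "non-CNS"),
                   "unannotated")
    return pd.DataFrame({
        "ID": v["id"], "CHR": v["chrom"], "POS": v["pos"],
        "EA": v["a1"], "OA": v["a0"],
        "BETA": beta_hat, "P": pvals, "CNS": cns,
    })


def _color_tilt_eta(config: SimulationConfig) -> float:
    """Log-odds tilt per SD calibrated to the configured quality effect.

    Colors are drawn with probability proportional to ``base_c *
    exp(eta * z * w_c)`` where w = (1, 0.5, 0) is the traffic-light weight;
    at z = 0 the derivative of the expected Healthy Purchasing Score is
    ``100 * eta * Var(w)``, so eta = effect_pts / (100 * Var(w)).
    """
    pg, py, pr = config.baseline_rates["color_probs"]
    w = np.array([1.0, 0.5, 0.0])
    probs = np.array([pg, py, pr])
    mean_w = probs @ w
    var_w = probs @ (w - mean_w) ** 2
    effect = config.purchase_effects["healthy_purchasing_score"]
    return effect / (100.0 * var_w)


def _weekday_offsets() -> dict:
    """offset->weekday-valid map: for each enrollment weekday, the offsets in
    1..91 whose date (enrollment - offset) falls Mon-Fri."""
    table = {}
    for we in range(7):
        offs = [o for o in range(1, BASELINE_DAYS + 1) if (we - o) % 7 < 5]
        table[we] = np.array(offs)
    return table


def simulate_phenotypes(genotypes: GenotypeMatrix, truth: GroundTruth,
                        config: SimulationConfig):
    """Simulate covariates (with BMI), transaction log, and survey table.

    Returns
    -------
    (covariates, transactions, survey) : pandas.DataFrame triple.  All
    realized effect coefficients are recorded in ``truth.true_effects``.
    """
    if len(truth.true_score) != genotypes.n_samples:
        raise ValueError("genotypes and ground truth are from different simulations")
    _, _, rng = _rngs(config)
    n = genotypes.n_samples
    z = truth.true_score
    ids = genotypes.samples
    rates = config.baseline_rates
    effects = config.purchase_effects

    # --- covariates -------------------------------------------------------
    age = np.clip(rng.normal(44.9, 12.8, n), 20, 75)
    female = rng.random(n) < 0.809
    start = np.datetime64(config.enrollment_window[0])
    end = np.datetime64(config.enrollment_window[1])
    span = (end - start).astype(int)
    enroll = start + rng.integers(0, span + 1, n).astype("timedelta64[D]")
    job = rng.choice(["administrative/service", "craft/technicians",
                      "management/professionals", "MDs/PhDs"],
                     n, p=np.array([0.091, 0.093, 0.713, 0.103]) / 1.0)
    edu = rng.choice(["high school/some college", "college degree", "graduate degree"],
                     n, p=np.array([0.081, 0.431, 0.488]))
    smoker = rng.random(n) < 0.025
    activity = rng.choice(["low", "moderate", "high"], n,
                          p=np.array([0.023, 0.280, 0.697]))

    bmi_beta = np.sqrt(config.bmi_h2 * config.bmi_residual_var)
    noise_sd = np.sqrt((1 - config.bmi_h2) * config.bmi_residual_var)
    bmi = (27.9 + bmi_beta * z + 0.02 * (age - 44.9) - 0.5 * female
           + rng.normal(0.0, noise_sd, n))

    covariates = pd.DataFrame({
        "participant_id": ids,
        "age": np.round(age, 1),
        "sex": np.where(female, "female", "male"),
        "enrollment_date": enroll.astype("datetime64[D]").astype(str),
        "bmi": bmi,
        "job_type": job,
        "education": edu,
        "current_smoker": smoker.astype(int),
        "physical_activity": activity,
    })

    # --- transaction log --------------------------------------------------
    mean_items = np.maximum(rates["items_per_3mo"] + effects["total_items"] * z, 1.0)
    k = float(rates["nb_dispersion"])
    counts = rng.negative_binomial(k, k / (k + mean_items))
    total = int(counts.sum())

    part_idx = np.repeat(np.arange(n), counts)
    z_item = z[part_idx]
    enroll_day = enroll.astype("datetime64[D]").astype(int)
    weekday = (enroll_day + 3) % 7  # 1970-01-01 was a Thursday
    offsets_by_wd = _weekday_offsets()
    n_wd = len(offsets_by_wd[0])
    off_pick = rng.integers(0, n_wd, total)
    offsets = np.empty(total, int)
    for wd, offs in offsets_by_wd.items():
        mask = weekday[part_idx] == wd
        offsets[mask] = offs[off_pick[mask]]
    day_int = enroll_day[part_idx] - offsets

    fb, fl, fo = (rates["food_frac_breakfast"], rates["food_frac_lunch"],
                  rates["food_frac_other"])
    slot_p = np.array([fb, fl, fo, 1.0 - fb - fl - fo])
    slot = rng.choice(4, total, p=slot_p)  # 0=breakfast food,1=lunch food,2=other food,3=beverage
    item_class = np.where(slot == 3, "beverage", "food")

    b_mean = rates["breakfast_time"] + effects["breakfast_time"] * z_item
    l_mean = rates["lunch_time"] + effects["lunch_time"] * z_item
    minutes = rng.integers(CAFETERIA_OPEN, CAFETERIA_CLOSE + 1, total).astype(float)
    bmask, lmask = slot == 0, slot == 1
    minutes[bmask] = np.clip(np.round(rng.normal(b_mean[bmask], 25.0)), 361, 599)
    minutes[lmask] = np.clip(np.round(rng.normal(l_mean[lmask], 25.0)), 661, 839)
    minutes = minutes.astype(int)

    eta = _color_tilt_eta(config)
    pg, py, pr = rates["color_probs"]
    wts = np.column_stack([pg * np.exp(eta * z_item * 1.0),
                           py * np.exp(eta * z_item * 0.5),
                           pr * np.ones(total)])
    cum = np.cumsum(wts, axis=1)
    u = rng.random(total) * cum[:, -1]
    color_idx = (u[:, None] > cum).sum(axis=1)
    color = np.array(["green", "yellow", "red"])[color_idx]
    color = np.where(rng.random(total) < rates["unlabeled_prob"], "unlabeled", color)

    ts = pd.to_datetime(day_int.astype("int64") * 86400 + minutes * 60, unit="s")
    transactions = pd.DataFrame({
        "participant_id": np.array(ids)[part_idx],
        "timestamp": ts,
        "item_id": [f"item{i:04d}" for i in rng.integers(0, 1200, total)],
        "item_class": item_class,
        "color": color,
    }).sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    # --- survey -----------------------------------------------------------
    survey = pd.DataFrame({"participant_id": ids})
    skip_cats = ["1–2 days", "3–4 days", "5–6 days", "Every day"]
    for col, eff_key in zip(SKIP_COLS, ("skips_breakfast", "skips_lunch", "skips_dinner")):
        p1 = expit(logit(rates[eff_key]) + effects[eff_key] * z)
        yes = rng.random(n) < p1
        cats = rng.choice(skip_cats, n, p=[0.5, 0.3, 0.15, 0.05])
        survey[col] = np.where(yes, cats, "Never")
    for col, eff_key in zip(HOME_COLS, ("prepares_breakfast_home",
                                        "prepares_lunch_home",
                                        "prepares_dinner_home")):
        p1 = expit(logit(rates[eff_key]) + effects[eff_key] * z)
        yes = rng.random(n) < p1
        hi = rng.choice(["3–4 days", "5–6 days", "Every day"], n, p=[0.5, 0.3, 0.2])
        lo = rng.choice(["Never", "1–2 days"], n, p=[0.5, 0.5])
        survey[col] = np.where(yes, hi, lo)

    truth.true_effects = {
        "bmi_beta_per_sd": float(bmi_beta),
        "bmi_h2": float(config.bmi_h2),
        "color_tilt_eta": float(eta),
        **{k: float(v) for k, v in effects.items()},
    }
    return covariates, transactions, survey


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate all five pipeline inputs plus ground truth from one config."""
    gm, truth = simulate_genotypes(config)
    weights = simulate_weights(gm, truth, config)
    covariates, transactions, survey = simulate_phenotypes(gm, truth, config)
    return SimulatedDataset(config=config, genotypes=gm, truth=truth,
                            weights=weights, covariates=covariates,
                            transactions=transactions, survey=survey)


def prs_weight_table(weights: pd.DataFrame, truth: GroundTruth,
                     genotypes: GenotypeMatrix,
                     n_cns: int = 54, n_noncns: int = 43) -> pd.DataFrame:
    """A fixed-loci PRS weight table from the simulated causal variants.

    Selects the ``n_cns + n_noncns`` causal variants with the largest true
    effects and assigns exactly ``n_cns`` CNS and ``n_noncns`` non-CNS flags
    (mirroring the 54/43 partition of the 97 published BMI loci).  Raises if
    the simulation has fewer causal variants than requested.
    """
    need = n_cns + n_noncns
    causal = np.flatnonzero(truth.causal_betas != 0)
    if len(causal) < need:
        raise ValueError(
            f"simulation has {len(causal)} causal variants; {need} required "
            "(raise frac_causal or n_variants)")
    order = causal[np.argsort(-np.abs(truth.causal_betas[causal]))][:need]
    ids = genotypes.variants.loc[np.sort(order), "id"]
    out = weights.set_index("ID").loc[ids].reset_index()
    out["CNS"] = ["CNS"] * n_cns + ["non-CNS"] * n_noncns
    return out


def write_dataset(ds: SimulatedDataset, outdir, write_vcf: bool = True) -> dict:
    """Write all dataset files; returns a name->path map.

    Ground truth goes to separate files never read by the pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(df, name, sep=","):
        p = outdir / name
        df.to_csv(p, sep=sep, index=False, float_format="%.6g")
        paths[name] = p

    ds.genotypes.write_tsv(outdir / "dosages.tsv", outdir / "variants.tsv")
    paths["dosages.tsv"] = outdir / "dosages.tsv"
    paths["variants.tsv"] = outdir / "variants.tsv"
    if write_vcf:
        ds.genotypes.write_vcf(outdir / "genotypes.vcf")
        paths["genotypes.vcf"] = outdir / "genotypes.vcf"
    _csv(ds.weights, "weights.tsv", sep="\t")
    tx = ds.transactions.copy()
    tx["timestamp"] = tx["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    _csv(tx, "transactions.csv")
    _csv(ds.survey, "survey.csv")
    _csv(ds.covariates, "covariates.csv")
    _csv(pd.DataFrame({"id": ds.genotypes.variants["id"],
                       "causal_beta": ds.truth.causal_betas}), "truth_variants.csv")
    _csv(pd.DataFrame({"participant_id": ds.genotypes.samples,
                       "true_score": ds.truth.true_score}), "truth_participants.csv")
    p = outdir / "truth_effects.json"
    p.write_text(json.dumps(ds.truth.true_effects, indent=2, sort_keys=True) + "\n")
    paths["truth_effects.json"] = p
    return paths
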