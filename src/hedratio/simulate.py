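"""Synthetic cohort generator for the HED analysis pipeline.

The study's patient data are not publicly deposited, so every input of the
pipeline is emulated here with the statistical structure the analysis
assumes: an aligned allele pool per locus, Hardy-Weinberg recipient
genotypes, donors matched by transplant category, clinical covariates with
the baseline category mix of a real transplant cohort, proportional-hazards
death/relapse times, GVHD and hematologic-recovery events, and log-normal
lymphocyte-subset counts.

Calibration targets are the reported study conditions: class I mean HED
near 7 and class II near 9.6 per subject, a 22/492 early-death fraction,
and the published covariate proportions.  All stages draw from sub-seeds
derived from one master seed by fixed offsets, so a seed reproduces every
output byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alleles import CLASS_I_LOCI, CLASS_II_LOCI, LOCI, AlleleName, AlleleStore
from .grantham import STANDARD_RESIDUES, GranthamMatrix, build_grantham_matrix
from .scoring import GENOTYPE_COLUMNS, SubjectGenotype, compute_profiles, profiles_table

IMMUNE_SUBSETS = ("NK", "CD8_total", "CD8_CM", "CD8_EM", "CD8_TE", "CD4", "B")


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """All parameters of the synthetic cohort (seeds, pools, effects)."""

    seed: int = 0
    n_subjects: int = 492

    # allele pools: class I alignments mimic exon 2+3 (~180 aa), class II
    # exon 2 (~90 aa); substitution counts calibrated so per-subject class I
    # mean HED sits near 7 and class II near 9.6
    pool_size: dict[str, int] = field(
        default_factory=lambda: {l: 14 for l in LOCI})
    locus_length: dict[str, int] = field(
        default_factory=lambda: {**{l: 180 for l in CLASS_I_LOCI},
                                 **{l: 90 for l in CLASS_II_LOCI}})
    substitutions: dict[str, int] = field(
        default_factory=lambda: {**{l: 7 for l in CLASS_I_LOCI},
                                 **{l: 5 for l in CLASS_II_LOCI}})
    dirichlet_concentration: float = 3.0  # allele-frequency dispersion

    # covariate category proportions (baseline mix of an AML HCT cohort)
    p_hla_match: dict[str, float] = field(default_factory=lambda: {
        "identical sibling": 0.3745, "matched unrelated": 0.3085,
        "mismatched unrelated": 0.2787, "haplo-identical": 0.0383})
    p_disease_status: dict[str, float] = field(default_factory=lambda: {
        "early": 0.750, "intermediate": 0.103, "advanced": 0.147})
    p_hct_number: dict[str, float] = field(default_factory=lambda: {
        "first": 0.913, "second_or_higher": 0.087})
    p_conditioning: dict[str, float] = field(default_factory=lambda: {
        "MAC": 0.40, "RIC": 0.60})
    p_graft_source: dict[str, float] = field(default_factory=lambda: {
        "BM": 0.198, "CB": 0.121, "PB": 0.681})
    p_tbi: dict[str, float] = field(default_factory=lambda: {
        "no": 0.719, "yes": 0.281})
    p_period: dict[str, float] = field(default_factory=lambda: {
        "2006-2010": 0.200, "2010-2015": 0.404, "2015-2019": 0.396})
    p_gender: dict[str, float] = field(default_factory=lambda: {
        "female": 0.455, "male": 0.545})
    p_diagnosis: dict[str, float] = field(default_factory=lambda: {
        "AML": 0.791, "MRC-AML": 0.209})

    # outcome model (per-day exponential baselines; Weibull shape optional)
    base_death_rate: float = 0.0008
    base_relapse_rate: float = 0.0009
    weibull_shape: float = 1.0
    score1_log_hr: float = 0.0  # effect of score1 > median on both hazards
    score1_effect: str = "dichotomized"  # or "linear"
    # optional direct per-unit log-HRs on centred HED variables, e.g.
    # {"classI_mean": -0.1, "hed_DQB1": 0.1}
    hed_log_hrs: dict[str, float] = field(default_factory=dict)
    control_log_hrs: dict[str, float] = field(default_factory=lambda: {
        "disease_status[intermediate]": 0.30,
        "disease_status[advanced]": 0.80,
        "hct_number[second_or_higher]": 0.35,
        "conditioning[RIC]": 0.10,
        "tbi[yes]": 0.00,
        "hla_match[matched unrelated]": 0.10,
        "hla_match[mismatched unrelated]": 0.30,
        "hla_match[haplo-identical]": 0.40,
        "graft_source[CB]": 0.20,
        "graft_source[PB]": 0.00,
    })
    censor_min_day: float = 90.0
    censor_max_day: float = 2600.0  # staggered entry over a ~13-year window
    early_death_frac: float = 22 / 492  # deaths placed before day 14

    # GVHD and recovery
    p_agvhd: dict[str, float] = field(default_factory=lambda: {
        "none": 0.427, "I": 0.242, "II": 0.162, "III": 0.096, "IV": 0.073})
    p_cgvhd: dict[str, float] = field(default_factory=lambda: {
        "none": 0.670, "limited": 0.175, "extensive": 0.155})

    # immune subcohort: log-mean/log-sd of counts (cells/uL) and the
    # additive log-shift in the high class I HED group at 12 months
    immune_n: int = 96
    immune_log_means: dict[str, float] = field(default_factory=lambda: {
        "NK": np.log(180.0), "CD8_total": np.log(400.0), "CD8_CM": np.log(60.0),
        "CD8_EM": np.log(150.0), "CD8_TE": np.log(120.0), "CD4": np.log(250.0),
        "B": np.log(150.0)})
    immune_log_sd: float = 0.6
    immune_hed_shift: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in IMMUNE_SUBSETS})

    def validate(self) -> None:
        for name in ("p_hla_match", "p_disease_status", "p_hct_number",
                     "p_conditioning", "p_graft_source", "p_tbi", "p_period",
                     "p_gender", "p_diagnosis", "p_agvhd", "p_cgvhd"):
            d = getattr(self, name)
            if any(not 0 <= v <= 1 for v in d.values()):
                raise SimError(f"{name}: probabilities must lie in [0,1]")
            if abs(sum(d.values()) - 1.0) > 1e-6:
                raise SimError(f"{name}: category proportions must sum to 1")
        if self.base_death_rate <= 0 or self.base_relapse_rate <= 0:
            raise SimError("hazard rates must be positive")
        if any(k < 1 for k in self.pool_size.values()):
            raise SimError("pool sizes must be >= 1")
        for locus in LOCI:
            if self.substitutions[locus] > self.locus_length[locus]:
                raise SimError(
                    f"{locus}: {self.substitutions[locus]} substitutions do not "
                    f"fit in alignment length {self.locus_length[locus]}; "
                    "divergence target unattainable")
        if not 0 <= self.early_death_frac < 1:
            raise SimError("early_death_frac must lie in [0,1)")


# sub-seed offsets: each generation stage is independently reproducible
_STAGE_OFFSET = {"pool": 1, "covariates": 2, "genotypes": 3, "outcomes": 4,
                 "immune": 5}


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(config.seed * 8 + _STAGE_OFFSET[stage])


# --- allele pool ------------------------------------------------------------

def simulate_allele_pool(
    config: SimConfig,
    fasta_path: str | Path | None = None,
) -> tuple[AlleleStore, dict[str, np.ndarray]]:
    """Generate per-locus allele pools and Dirichlet allele frequencies.

    Each locus gets a random ancestral sequence; alleles are derived by
    seeded point substitutions at distinct positions, which makes the
    pairwise divergence distribution controllable through the substitution
    count.  Class II pools are built with a higher per-site substitution
    density than class I, so class II mean pairwise HED exceeds class I.
    Returns the store plus allele frequencies; optionally writes FASTA.
    """
    config.validate()
    rng = _rng(config, "pool")
    residues = np.array(list(STANDARD_RESIDUES))
    store = AlleleStore()
    freqs: dict[str, np.ndarray] = {}
    for locus in LOCI:
        length = config.locus_length[locus]
        k_pool = config.pool_size[locus]
        ancestor = rng.choice(residues, size=length)
        for a in range(k_pool):
            seq = ancestor.copy()
            positions = rng.choice(length, size=config.substitutions[locus],
                                   replace=False)
            for pos in positions:
                choices = [r for r in STANDARD_RESIDUES if r != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
            name = AlleleName(locus, f"{a + 1:02d}", "01")
            store.add(name, "".join(seq))
        freqs[locus] = (
            rng.dirichlet([config.dirichlet_concentration] * k_pool)
            if k_pool > 1 else np.array([1.0])
        )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for locus in LOCI:
                for name in store.alleles_at(locus):
                    fh.write(f">{name} class={'I' if locus in CLASS_I_LOCI else 'II'}\n")
                    fh.write(store.sequence(name) + "\n")
    return store, freqs


# --- genotypes --------------------------------------------------------------

def simulate_genotypes(
    config: SimConfig,
    store: AlleleStore,
    freqs: dict[str, np.ndarray],
    hla_match: np.ndarray,
) -> tuple[list[SubjectGenotype], list[SubjectGenotype]]:
    """Recipient genotypes under Hardy-Weinberg; donors per match category.

    identical sibling: donor = recipient.  matched unrelated (10/10): all
    loci copied except DPB1, resampled independently.  mismatched unrelated
    (9/10): copy, then one allele at one random class I locus replaced by a
    different allele.  haplo-identical: first haplotype shared, second
    resampled at every locus.
    """
    rng = _rng(config, "genotypes")
    names = {l: store.alleles_at(l) for l in LOCI}
    recipients, donors = [], []

    def draw(locus) -> AlleleName:
        return names[locus][rng.choice(len(names[locus]), p=freqs[locus])]

    for i, match in enumerate(hla_match):
        sid = f"S{i + 1:04d}"
        r_pairs = {l: (draw(l), draw(l)) for l in LOCI}
        d_pairs = {l: r_pairs[l] for l in LOCI}
        if match == "matched unrelated":
            d_pairs["DPB1"] = (draw("DPB1"), draw("DPB1"))
        elif match == "mismatched unrelated":
            locus = CLASS_I_LOCI[rng.integers(3)]
            slot = rng.integers(2)
            old = d_pairs[locus][slot]
            candidates = [n for n in names[locus] if n != old]
            new = candidates[rng.integers(len(candidates))] if candidates else old
            pair = list(d_pairs[locus])
            pair[slot] = new
            d_pairs[locus] = tuple(pair)
        elif match == "haplo-identical":
            d_pairs = {l: (r_pairs[l][0], draw(l)) for l in LOCI}
        elif match != "identical sibling":
            raise SimError(f"unknown hla_match category {match!r}")
        recipients.append(SubjectGenotype(sid, "recipient", r_pairs))
        donors.append(SubjectGenotype(sid, "donor", d_pairs))
    return recipients, donors


def genotypes_frame(genotypes: list[SubjectGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        row = {"subject_id": g.subject_id, "role": g.role}
        for locus in LOCI:
            pair = g.allele_pairs.get(locus)
            row[f"{locus}_1"] = str(pair[0]) if pair else ""
            row[f"{locus}_2"] = str(pair[1]) if pair else ""
        rows.append(row)
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


# --- covariates and outcomes ------------------------------------------------

def _sample_categories(rng, n, proportions: dict[str, float]) -> np.ndarray:
    levels = list(proportions)
    p = np.array([proportions[l] for l in levels])
    return rng.choice(levels, size=n, p=p / p.sum())


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    rng = _rng(config, "covariates")
    n = config.n_subjects
    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "age": np.clip(rng.normal(48.5, 13.5, n), 18, 75).round(1),
        "gender": _sample_categories(rng, n, config.p_gender),
        "diagnosis": _sample_categories(rng, n, config.p_diagnosis),
        "disease_status": _sample_categories(rng, n, config.p_disease_status),
        "hct_number": _sample_categories(rng, n, config.p_hct_number),
        "hct_period": _sample_categories(rng, n, config.p_period),
        "graft_source": _sample_categories(rng, n, config.p_graft_source),
        "hla_match": _sample_categories(rng, n, config.p_hla_match),
        "conditioning": _sample_categories(rng, n, config.p_conditioning),
        "tbi": _sample_categories(rng, n, config.p_tbi),
    })
    return df


def simulate_outcomes(
    cohort: pd.DataFrame,
    recipient_profiles: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Attach survival, GVHD, recovery and immune columns to the cohort.

    Death and relapse times are exponential (Weibull if shape != 1) with
    log-rates linear in the control covariates plus the score1 effect;
    censoring is administrative at a staggered per-subject horizon.  A
    configured fraction of subjects (rounded to a whole count, so the
    number is deterministic) is converted to early deaths before day 14 to
    exercise the exclusion filter.
    """
    config.validate()
    rng = _rng(config, "outcomes")
    hed_cols = [f"hed_{l}" for l in LOCI] + [
        "classI_mean", "classII_mean", "score1", "score2", "score3", "score4"]
    df = cohort.merge(
        recipient_profiles.loc[
            recipient_profiles["role"] == "recipient", ["subject_id"] + hed_cols],
        on="subject_id", how="left",
    )
    n = len(df)

    score1 = df["score1"].to_numpy(dtype=float)
    med = np.nanmedian(score1)
    high = np.where(np.isnan(score1), 0.0, (score1 > med).astype(float))
    if config.score1_effect == "dichotomized":
        score_term = config.score1_log_hr * high
    elif config.score1_effect == "linear":
        centered = np.where(np.isnan(score1), 0.0, score1 - med)
        score_term = config.score1_log_hr * centered
    else:
        raise SimError(f"unknown score1_effect {config.score1_effect!r}")

    lp = score_term.copy()
    for var, beta in config.hed_log_hrs.items():
        vals = df[var].to_numpy(dtype=float)
        centred = np.where(np.isnan(vals), 0.0, vals - np.nanmean(vals))
        lp += beta * centred
    for key, beta in config.control_log_hrs.items():
        var, level = key[:-1].split("[")
        lp += beta * (df[var] == level).to_numpy(dtype=float)

    def draw_times(base_rate):
        u = rng.exponential(1.0, n)
        t = u / (base_rate * np.exp(lp))
        if config.weibull_shape != 1.0:
            t = t ** (1.0 / config.weibull_shape) * (1 / base_rate) ** (
                1 - 1 / config.weibull_shape)
        return t

    death = draw_times(config.base_death_rate)
    relapse = draw_times(config.base_relapse_rate)
    censor = rng.uniform(config.censor_min_day, config.censor_max_day, n)

    # early deaths are governed solely by early_death_frac: natural draws
    # below day 14 are deferred to day 14, then an exact rounded count of
    # subjects is converted, so the exclusion accounting is deterministic
    death = np.maximum(death, 14.0)
    n_early = int(round(config.early_death_frac * n))
    early_idx = rng.choice(n, size=n_early, replace=False)
    death[early_idx] = rng.integers(1, 14, size=n_early).astype(float)
    censor[early_idx] = np.maximum(censor[early_idx], 14.0)

    death_obs = death <= censor
    followup = np.where(death_obs, death, censor).round(0)
    death_day = np.where(death_obs, followup, np.nan)
    relapse_obs = (relapse < np.minimum(death, censor))
    relapse_day = np.where(relapse_obs, np.minimum(relapse.round(0), followup), np.nan)
    relapse_day = np.where(relapse_day < 1, 1.0, relapse_day)

    df["death_day"] = death_day
    df["relapse_day"] = relapse_day
    df["last_followup_day"] = followup

    # GVHD: grade drawn from the configured mix, onset windows typical of
    # acute (first 100 days) and chronic (after day 100) disease
    agvhd = _sample_categories(rng, n, config.p_agvhd)
    agvhd_onset = rng.uniform(10, 100, n).round(0)
    cgvhd = _sample_categories(rng, n, config.p_cgvhd)
    cgvhd_onset = rng.uniform(100, 450, n).round(0)
    too_late = agvhd_onset > followup
    agvhd[too_late] = "none"
    agvhd_onset = np.where((agvhd == "none") | too_late, np.nan, agvhd_onset)
    too_late_c = cgvhd_onset > followup
    cgvhd[too_late_c] = "none"
    cgvhd_onset = np.where((cgvhd == "none") | too_late_c, np.nan, cgvhd_onset)
    df["agvhd_grade"] = agvhd
    df["agvhd_onset_day"] = agvhd_onset
    df["cgvhd"] = cgvhd
    df["cgvhd_onset_day"] = cgvhd_onset

    neut = np.clip(rng.normal(18, 4, n), 8, 60).round(0)
    plt_ = np.clip(rng.normal(25, 8, n), 10, 90).round(0)
    df["neutrophil_recovery_day"] = np.where(neut <= followup, neut, np.nan)
    df["platelet_recovery_day"] = np.where(plt_ <= followup, plt_, np.nan)

    # immune subcohort: survivors sampled for flow-cytometry counts
    rng_imm = _rng(config, "immune")
    for months, day in ((6, 183), (12, 365)):
        alive = df.index[(df["last_followup_day"] >= day)
                         & (df["death_day"].isna() | (df["death_day"] > day))]
        take = min(config.immune_n, len(alive))
        chosen = rng_imm.choice(alive.to_numpy(), size=take, replace=False)
        ci = df.loc[chosen, "classI_mean"].to_numpy(dtype=float)
        hi = (ci > np.nanmedian(ci)).astype(float)
        for subset in IMMUNE_SUBSETS:
            mu = config.immune_log_means[subset] + (
                config.immune_hed_shift[subset] * hi if months == 12 else 0.0)
            counts = np.exp(rng_imm.normal(mu, config.immune_log_sd))
            col = f"{subset}_m{months}"
            df[col] = np.nan
            df.loc[chosen, col] = counts.round(1)
    return df


# --- orchestrator -----------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    store: AlleleStore
    frequencies: dict[str, np.ndarray]
    recipients: list[SubjectGenotype]
    donors: list[SubjectGenotype]
    profiles: pd.DataFrame  # recipients and donors, with group labels
    cohort: pd.DataFrame    # covariates + outcomes + recipient HED columns


def simulate_cohort(config: SimConfig | None = None, **overrides) -> SimResult:
    """Run every generation stage and return all tables.

    ``overrides`` are applied to the default :class:`SimConfig` via
    dataclass replace, e.g. ``simulate_cohort(seed=3, score1_log_hr=np.log(0.4))``.
    """
    config = replace(config or SimConfig(), **overrides)
    config.validate()
    matrix = build_grantham_matrix()
    store, freqs = simulate_allele_pool(config)
    covariates = simulate_covariates(config)
    recipients, donors = simulate_genotypes(
        config, store, freqs, covariates["hla_match"].to_numpy())
    profiles = profiles_table(
        compute_profiles(recipients + donors, store, matrix))
    cohort = simulate_outcomes(covariates, profiles, config)
    return SimResult(config, store, freqs, recipients, donors, profiles, cohort)


def write_simulation(result: SimResult, out_dir: str | Path) -> None:
    """Write store.fasta, genotypes.tsv, cohort.tsv and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "store.fasta", "w") as fh:
        for locus in LOCI:
            for name in result.store.alleles_at(locus):
                cls = "I" if locus in CLASS_I_LOCI else "II"
                fh.write(f">{name} class={cls}\n{result.store.sequence(name)}\n")
    genotypes_frame(result.recipients + result.donors).to_csv(
        out / "genotypes.tsv", sep="\t", index=False)
    result.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    result.profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    with open(out / "manifest.txt", "w") as fh:
        fh.write(f"seed = {result.config.seed}\n")
        fh.write(f"n_subjects = {result.config.n_subjects}\n")
        fh.write(f"score1_log_hr = {result.config.score1_log_hr}\n")
        fh.write(f"early_death_frac = {result.config.early_death_frac}\n")
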