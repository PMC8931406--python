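"""Per-subject HED profiles and ratio scores.

The HED of one locus is the per-site Grantham divergence between a
subject's two allele sequences at that locus (0 for homozygotes).  Class
means average the available loci of each class: class I over A, B, C and
class II over DRB1, DQB1, DPB1.  Four ratio scores combine them, with CI
denoting the class I mean:

    score1 = CI / classII_mean
    score2 = (CI + HED_DRB1) / HED_DQB1
    score3 = (CI + HED_DPB1) / HED_DQB1
    score4 = (CI + HED_DPB1) / (HED_DQB1 + HED_DRB1)

"class I + DRB1" is read literally as the class I mean plus the
single-locus HED (see docs/methods.md for the alternative reading).  A zero
denominator (fully homozygous class II) yields a missing score, never an
infinity — missing values are never imputed downstream.  Stratification
offers a median split (ties go low) and an empirical-quantile tercile
split.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alleles import (
    CLASS_I_LOCI,
    CLASS_II_LOCI,
    LOCI,
    AlleleName,
    AlleleStore,
    parse_allele_name,
    resolve_sequence,
)
from .grantham import GranthamMatrix, pairwise_sequence_hed

logger = logging.getLogger(__name__)

SCORE_NAMES = ("score1", "score2", "score3", "score4")


class ProfileError(ValueError):
    pass


@dataclass
class SubjectGenotype:
    """Two alleles at each typed locus for one recipient or donor."""

    subject_id: str
    role: str  # "recipient" | "donor"
    allele_pairs: dict[str, tuple[AlleleName, AlleleName]] = field(default_factory=dict)

    @property
    def typed_loci(self) -> list[str]:
        return [l for l in LOCI if l in self.allele_pairs]

    def validate(self) -> None:
        if self.role not in ("recipient", "donor"):
            raise ProfileError(f"{self.subject_id}: invalid role {self.role!r}")
        if not any(l in self.allele_pairs for l in CLASS_I_LOCI) or not any(
            l in self.allele_pairs for l in CLASS_II_LOCI
        ):
            raise ProfileError(
                f"{self.subject_id}: needs at least one typed class I and one "
                "typed class II locus for a usable profile"
            )


@dataclass
class HEDProfile:
    """Per-locus HED, class means and ratio scores for one subject."""

    subject_id: str
    role: str
    locus_hed: dict[str, float | None]
    classI_mean: float
    classII_mean: float
    scores: dict[str, float | None]
    complete: bool  # all six loci typed
    expanded_loci: list[str]  # loci where a 1-field typing was expanded

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "role": self.role}
        for locus in LOCI:
            row[f"hed_{locus}"] = self.locus_hed.get(locus)
        row["classI_mean"] = self.classI_mean
        row["classII_mean"] = self.classII_mean
        row.update(self.scores)
        row["complete"] = self.complete
        return row


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def locus_hed(
    genotype: SubjectGenotype,
    locus: str,
    store: AlleleStore,
    matrix: GranthamMatrix,
    policy: str = "smallest",
    frequencies=None,
) -> float | None:
    """Per-site divergence between the two allele copies at one locus.

    Returns None when the locus is untyped.  Lookup failures are re-raised
    with the subject id attached.
    """
    pair = genotype.allele_pairs.get(locus)
    if pair is None:
        return None
    try:
        seq_a, _ = resolve_sequence(pair[0], store, policy, frequencies)
        seq_b, _ = resolve_sequence(pair[1], store, policy, frequencies)
    except Exception as exc:
        raise type(exc)(f"subject {genotype.subject_id} ({genotype.role}): {exc}")
    if pair[0] == pair[1]:
        return 0.0
    return pairwise_sequence_hed(seq_a, seq_b, matrix)


def compute_profile(
    genotype: SubjectGenotype,
    store: AlleleStore,
    matrix: GranthamMatrix,
    policy: str = "smallest",
    frequencies=None,
) -> HEDProfile:
    """All per-locus HEDs, class means over typed loci, and scores 1-4."""
    hed: dict[str, float | None] = {}
    expanded = []
    for locus in LOCI:
        pair = genotype.allele_pairs.get(locus)
        hed[locus] = locus_hed(genotype, locus, store, matrix, policy, frequencies)
        if pair is not None and any(a.resolution == 1 for a in pair):
            expanded.append(locus)
    return _assemble_profile(genotype, hed, expanded)


def _assemble_profile(
    genotype: SubjectGenotype,
    hed: dict[str, float | None],
    expanded: list[str],
) -> HEDProfile:
    genotype.validate()
    ci_vals = [hed[l] for l in CLASS_I_LOCI if hed[l] is not None]
    cii_vals = [hed[l] for l in CLASS_II_LOCI if hed[l] is not None]
    ci = float(np.mean(ci_vals))
    cii = float(np.mean(cii_vals))

    def ratio(num: float | None, den: float | None) -> float | None:
        if _is_missing(num) or _is_missing(den):
            return None
        if den == 0:
            logger.warning(
                "%s (%s): zero denominator, score set to missing",
                genotype.subject_id, genotype.role,
            )
            return None
        return num / den

    def plus(*terms):
        if any(_is_missing(t) for t in terms):
            return None
        return sum(terms)

    scores = {
        "score1": ratio(ci, cii),
        "score2": ratio(plus(ci, hed["DRB1"]), hed["DQB1"]),
        "score3": ratio(plus(ci, hed["DPB1"]), hed["DQB1"]),
        "score4": ratio(plus(ci, hed["DPB1"]), plus(hed["DQB1"], hed["DRB1"])),
    }
    return HEDProfile(
        subject_id=genotype.subject_id,
        role=genotype.role,
        locus_hed=hed,
        classI_mean=ci,
        classII_mean=cii,
        scores=scores,
        complete=len(genotype.typed_loci) == len(LOCI),
        expanded_loci=expanded,
    )


def compute_profiles(
    genotypes: list[SubjectGenotype],
    store: AlleleStore,
    matrix: GranthamMatrix,
    policy: str = "smallest",
    frequencies=None,
) -> list[HEDProfile]:
    """Batch profile computation with a per-locus pair cache.

    Cohorts draw alleles from a pool far smaller than the subject count, so
    caching the divergence of each unordered allele pair makes profiling
    O(pool^2) in sequence comparisons instead of O(n).
    """
    cache: dict[tuple[AlleleName, AlleleName], float] = {}
    profiles = []
    for g in genotypes:
        hed: dict[str, float | None] = {}
        expanded = []
        for locus in LOCI:
            pair = g.allele_pairs.get(locus)
            if pair is None:
                hed[locus] = None
                continue
            key = tuple(sorted(pair))
            if key not in cache:
                cache[key] = locus_hed(g, locus, store, matrix, policy, frequencies)
            hed[locus] = cache[key]
            if any(a.resolution == 1 for a in pair):
                expanded.append(locus)
        profiles.append(_assemble_profile(g, hed, expanded))
    return profiles


def stratify(values, scheme: str = "median") -> list[str]:
    """Group labels for a sequence of values with missing entries.

    median: value <= median -> "low", else "high".  tercile: three groups
    split at the empirical 1/3 and 2/3 quantiles (linear interpolation),
    left-closed so a value equal to a cut point falls in the lower group.
    Missing values are labelled "missing", never imputed.
    """
    arr = np.array(
        [np.nan if _is_missing(v) else float(v) for v in values], dtype=float
    )
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ProfileError("stratify: all values missing")
    labels: list[str] = []
    if scheme == "median":
        med = float(np.median(obs))
        for v in arr:
            labels.append("missing" if np.isnan(v) else ("low" if v <= med else "high"))
    elif scheme == "tercile":
        q1, q2 = np.quantile(obs, [1 / 3, 2 / 3])
        for v in arr:
            if np.isnan(v):
                labels.append("missing")
            elif v <= q1:
                labels.append("low")
            elif v <= q2:
                labels.append("mid")
            else:
                labels.append("high")
    else:
        raise ProfileError(f"unknown stratification scheme {scheme!r}")
    return labels


# --- genotype table IO -----------------------------------------------------

GENOTYPE_COLUMNS = ["subject_id", "role"] + [
    f"{locus}_{i}" for locus in LOCI for i in (1, 2)
]


def read_genotypes(path: str | Path) -> list[SubjectGenotype]:
    """Read a genotype TSV (one row per subject x role).

    Columns: subject_id, role, then <locus>_1/<locus>_2 for the six loci;
    an empty cell at either allele column marks the locus untyped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ProfileError(f"genotype table missing columns: {sorted(missing_cols)}")
    genotypes = []
    for _, row in df.iterrows():
        pairs = {}
        for locus in LOCI:
            a1, a2 = row[f"{locus}_1"], row[f"{locus}_2"]
            if pd.isna(a1) or pd.isna(a2) or not str(a1).strip() or not str(a2).strip():
                continue
            pairs[locus] = (parse_allele_name(str(a1)), parse_allele_name(str(a2)))
        genotypes.append(SubjectGenotype(str(row["subject_id"]), str(row["role"]), pairs))
    return genotypes


def profiles_table(profiles: list[HEDProfile]) -> pd.DataFrame:
    """Tabulate profiles and attach median/tercile group labels per role.

    Labels are computed within each role so recipient and donor cut points
    stay independent.
    """
    df = pd.DataFrame([p.as_row() for p in profiles])
    for col in ("classI_mean", "score1"):
        for scheme, suffix in (("median", "group"), ("tercile", "tercile")):
            out = pd.Series(index=df.index, dtype=object)
            for role in df["role"].unique():
                mask = df["role"] == role
                try:
                    out[mask] = stratify(df.loc[mask, col], scheme)
                except ProfileError:  # degenerate: no usable value in role
                    out[mask] = "missing"
            df[f"{col}_{suffix}"] = out
    return df
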