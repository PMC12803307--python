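"""Synthetic fixtures for every input the tool consumes.

The generator emulates, at configurable scale: an ICD-9/10 catalogue with
free-text descriptions, Phecode-style phenotype definitions with a
two-level parent hierarchy and 18 category labels, per-person diagnosis
records with same-day multi-code events, and sex/ancestry strata.

Semantic signal is controllable by construction: each phenotype owns a
disjoint group of three "concept" tokens that form its query name; a
member code's description contains those tokens with probability
``signal_rate`` and a non-member picks up a random phenotype's concept
token with probability ``noise_rate``.  Because the toy hashing encoder
scores token overlap, these two rates directly control how separable
relevant codes are — retrieval and fusion behaviour is predictable
offline, with no pretrained models.

Reference-set sizes follow a log-normal law, mirroring the strong right
skew of real Phecode definitions (median 28, IQR 18–59 among non-trivial
phenotypes; roughly two-thirds of all phenotypes have ≤ 10 codes).  Two
presets encode those two regimes; see :meth:`SynthConfig.trivial_inclusive`
and :meth:`SynthConfig.nontrivial`.

Everything is a pure function of the config (which includes the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import IcdCatalog, IcdCode, PhenotypeDefinition
from .exceptions import ConfigurationError

CATEGORIES = (
    "Blood/Immune", "Cardiovascular", "Congenital", "Dermatological",
    "Endocrine", "Gastrointestinal", "Genetic", "Genitourinary",
    "Infections", "Mental", "Metabolic", "Musculoskeletal",
    "Neoplasms", "Neurological", "Pregnancy", "Respiratory",
    "Sense organs", "Symptoms",
)

_N_BACKGROUND = 400
_CONCEPT_TOKENS = 3
_EPOCH = np.datetime64("2015-01-01")
_DAY_SPAN = 2000


@dataclass(frozen=True)
class SynthConfig:
    """Stated world for one synthetic dataset."""

    seed: int
    n_codes: int = 5000
    vocab_mix: float = 0.35          # fraction of codes drawn as ICD-9-CM
    n_phenotypes: int = 100
    size_median: float = 28.0        # log-normal median of reference-set size
    size_sigma: float = 0.75         # log-normal shape
    min_size: int = 2                # sizes below this are resampled
    signal_rate: float = 0.9
    noise_rate: float = 0.05
    n_persons: int = 1000
    records_per_person: float = 8.0  # Poisson mean
    sex_proportions: tuple = (("F", 0.5), ("M", 0.5))
    ancestry_proportions: tuple = (("EUR", 0.6), ("AFR", 0.25), ("HIS", 0.15))

    def __post_init__(self) -> None:
        for name in ("vocab_mix", "signal_rate", "noise_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.n_codes < 1 or self.n_phenotypes < 1 or self.n_persons < 0:
            raise ConfigurationError("n_codes, n_phenotypes must be positive")
        if self.min_size < 1 or self.size_median <= 0 or self.size_sigma <= 0:
            raise ConfigurationError("invalid size distribution parameters")
        for props in (self.sex_proportions, self.ancestry_proportions):
            total = sum(p for _, p in props)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(f"stratum proportions must sum to 1, got {total}")

    @classmethod
    def trivial_inclusive(cls, seed: int, **overrides) -> "SynthConfig":
        """Full-skew preset: ~two-thirds of phenotypes have ≤ 10 codes.

        Log-normal median 7, sigma 1.0: P(size ≤ 10) = Φ(ln(10/7)) ≈ 0.64.
        """
        return cls(seed=seed, size_median=7.0, size_sigma=1.0, min_size=2, **overrides)

    @classmethod
    def nontrivial(cls, seed: int, **overrides) -> "SynthConfig":
        """Non-trivial preset: sizes > 10, median ≈ 28 as in real benchmarks."""
        return cls(seed=seed, size_median=28.0, size_sigma=0.75, min_size=11, **overrides)


def _sample_sizes(rng: np.random.Generator, config: SynthConfig) -> np.ndarray:
    mu = math.log(config.size_median)
    sizes = np.zeros(config.n_phenotypes, dtype=np.int64)
    pending = np.arange(config.n_phenotypes)
    while pending.size:
        draw = np.rint(rng.lognormal(mu, config.size_sigma, pending.size)).astype(np.int64)
        ok = draw >= config.min_size
        sizes[pending[ok]] = draw[ok]
        pending = pending[~ok]
    return sizes


def _code_string(vocab: str, counter: int) -> str:
    if vocab == "ICD9CM":
        return f"{100 + counter % 900}.{counter // 900}"
    letter = chr(ord("A") + counter % 26)
    return f"{letter}{(counter // 26) % 100:02d}.{counter // 2600}"


def make_catalog_and_phenotypes(
    config: SynthConfig,
) -> tuple[IcdCatalog, list[PhenotypeDefinition]]:
    """Generate the catalogue and phenotype definitions for one world."""
    rng = np.random.default_rng([config.seed, 0])
    sizes = _sample_sizes(rng, config)
    if sizes.max() > config.n_codes:
        raise ConfigurationError(
            f"largest phenotype ({sizes.max()} codes) exceeds catalogue size {config.n_codes}"
        )

    # tokens are random letter strings: shared prefixes (e.g. a cpt001/cpt002
    # scheme) would leak character 3-grams across concept groups and break
    # the intended disjointness in hashed-feature space
    def rand_token() -> str:
        return "".join(chr(97 + c) for c in rng.integers(0, 26, 8))

    background = [rand_token() for _ in range(_N_BACKGROUND)]
    concept = [
        [rand_token() for _ in range(_CONCEPT_TOKENS)]
        for _ in range(config.n_phenotypes)
    ]

    # per-code token assembly: background base, plus concept tokens from
    # phenotype membership (signal) or random contamination (noise)
    code_tokens: list[list[str]] = []
    counters = {"ICD9CM": 0, "ICD10CM": 0}
    vocabularies: list[str] = []
    codes: list[str] = []
    for i in range(config.n_codes):
        vocab = "ICD9CM" if rng.random() < config.vocab_mix else "ICD10CM"
        vocabularies.append(vocab)
        codes.append(_code_string(vocab, counters[vocab]))
        counters[vocab] += 1
        n_bg = int(rng.integers(3, 6))
        code_tokens.append(list(rng.choice(background, n_bg, replace=False)))

    members: list[np.ndarray] = []
    for p in range(config.n_phenotypes):
        idx = rng.choice(config.n_codes, sizes[p], replace=False)
        members.append(np.sort(idx))
        for code_idx in idx:
            if rng.random() < config.signal_rate:
                code_tokens[code_idx] = concept[p] + code_tokens[code_idx]
    for i in range(config.n_codes):
        if rng.random() < config.noise_rate:
            p = int(rng.integers(config.n_phenotypes))
            code_tokens[i].append(concept[p][int(rng.integers(_CONCEPT_TOKENS))])

    entries = [
        IcdCode(vocabularies[i], codes[i], " ".join(code_tokens[i]))
        for i in range(config.n_codes)
    ]
    catalog = IcdCatalog(entries)
    keys = catalog.keys

    definitions = []
    for p in range(config.n_phenotypes):
        parent = f"SB_{p - 1:03d}" if p % 3 == 1 else None
        definitions.append(
            PhenotypeDefinition(
                phenotype_id=f"SB_{p:03d}",
                name=" ".join(concept[p]) + " disorder",
                category=CATEGORIES[p % len(CATEGORIES)],
                parent_id=parent,
                icd_set=frozenset(keys[i] for i in members[p]),
            )
        )
    return catalog, definitions


def make_diagnosis_records(
    config: SynthConfig,
    catalog: IcdCatalog,
    phenotypes: list[PhenotypeDefinition],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-person diagnosis records and a strata table.

    Each person has an affinity phenotype supplying ~80% of their codes;
    every fifth person gets a deliberate same-day multi-code pair so that
    calendar-day collapsing is always exercised.
    """
    rng = np.random.default_rng([config.seed, 1])
    keys = catalog.keys
    sex_labels, sex_p = zip(*config.sex_proportions)
    anc_labels, anc_p = zip(*config.ancestry_proportions)

    strata_rows = []
    record_rows = []
    for i in range(config.n_persons):
        pid = f"P{i:05d}"
        strata_rows.append(
            {
                "person_id": pid,
                "sex": str(rng.choice(sex_labels, p=sex_p)),
                "ancestry": str(rng.choice(anc_labels, p=anc_p)),
            }
        )
        affinity = sorted(phenotypes[int(rng.integers(len(phenotypes)))].icd_set)
        n_rec = 1 + int(rng.poisson(max(config.records_per_person - 1, 0)))
        days = rng.integers(0, _DAY_SPAN, n_rec)
        person_records = []
        for d in days:
            if rng.random() < 0.8:
                vocab, code = affinity[int(rng.integers(len(affinity)))]
            else:
                vocab, code = keys[int(rng.integers(len(keys)))]
            hour = int(rng.integers(0, 24))
            stamp = (_EPOCH + np.timedelta64(int(d), "D")).astype("datetime64[s]")
            person_records.append(
                {
                    "person_id": pid,
                    "vocabulary": vocab,
                    "code": code,
                    "event_time": f"{stamp}".split("T")[0] + f"T{hour:02d}:00:00",
                }
            )
        if i % 5 == 0 and person_records:
            first = person_records[0]
            vocab, code = affinity[int(rng.integers(len(affinity)))]
            person_records.append({**first, "vocabulary": vocab, "code": code})
        record_rows.extend(person_records)

    records = pd.DataFrame(record_rows, columns=["person_id", "vocabulary", "code", "event_time"])
    strata = pd.DataFrame(strata_rows, columns=["person_id", "sex", "ancestry"])
    return records, strata


def definitions_to_frame(definitions: list[PhenotypeDefinition]) -> pd.DataFrame:
    """Long-format definition table (one row per phenotype × member code)."""
    rows = []
    for d in definitions:
        for vocab, code in sorted(d.icd_set):
            rows.append(
                {
                    "phecode": d.phenotype_id,
                    "phecode_string": d.name,
                    "category": d.category,
                    "parent": d.parent_id or "",
                    "vocabulary": vocab,
                    "code": code,
                }
            )
    return pd.DataFrame(rows)
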