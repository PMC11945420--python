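"""Synthetic spontaneous-report and descriptor-matrix generators.

Real pharmacovigilance work starts from the FDA Adverse Event Reporting
System (FAERS) quarterly extracts and from proprietary descriptor software.
Neither is redistributable, so this module generates report tables in the
FAERS shape (Drug / Reaction / Demographic / Therapy) with planted
disproportionality signals, and drugs-by-descriptors matrices with a known
class structure.  Every planted property is returned as ground truth so the
downstream extract-transform-load (ETL), signal-detection and modeling
stages can be tested against a known answer.

The report generator plants each positive drug so that its odds of carrying
the target event equal ``lift`` times the background odds — i.e. the
population reporting odds ratio of a planted drug *is* its lift.  It also
emulates the data pathologies the ETL stage must handle: exact duplicate
submissions with an incremented case version, therapy/onset date triples
that violate the start <= onset <= end ordering, and concomitant-drug rows
that must be removed by the suspect-role filter.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# Target adverse-event preferred term used throughout the pipeline.
TARGET_EVENT_TERM = "osteonecrosis of the jaw"

# Toy vocabularies; the pipeline only needs *some* controlled strings here.
_BACKGROUND_TERMS = (
    "nausea", "headache", "dizziness", "rash", "fatigue", "vomiting",
    "diarrhoea", "pyrexia", "pruritus", "insomnia", "arthralgia", "anaemia",
)
_ATC_CLASSES = (
    "M05B", "L01E", "L02B", "L04A", "H02A", "A11C", "C05A", "D07A",
    "J01D", "N02B", "R01A", "S01B",
)

_DATE_ORIGIN = np.datetime64("2005-01-01")
_DATE_SPAN_DAYS = 6000  # therapy starts drawn from ~16 years


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one global seed out to independent child streams.

    Children are ``SeedSequence(seed).spawn(n)`` in a fixed order, so
    regenerating a single table is stable for a given global seed.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Report-table simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Conditions for one synthetic spontaneous-report database.

    ``target_event_rate`` is the background fraction of reports carrying the
    target event (default 2.7e-4, the headline rarity of osteonecrosis of
    the jaw among all reports).  ``planted_positive_drugs`` /
    ``planted_negative_drugs`` map drug names to odds lifts (>1 raises the
    drug's target-event odds, <1 lowers them).  Per-drug report totals are
    heterogeneous: drawn from a log-normal with shape ``report_count_sigma``.
    """

    n_drugs: int = 50
    n_reports: int = 100_000
    target_event_rate: float = 0.00027
    planted_positive_drugs: dict[str, float] = field(default_factory=dict)
    planted_negative_drugs: dict[str, float] = field(default_factory=dict)
    report_count_sigma: float = 1.0
    date_inconsistency_fraction: float = 0.05
    duplicate_fraction: float = 0.02
    concomitant_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("target_event_rate", self.target_event_rate),
            ("date_inconsistency_fraction", self.date_inconsistency_fraction),
            ("duplicate_fraction", self.duplicate_fraction),
            ("concomitant_fraction", self.concomitant_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.n_drugs < 1:
            raise ConfigurationError("n_drugs must be positive")
        if self.n_reports < self.n_drugs:
            raise ConfigurationError("n_reports must be >= n_drugs")
        for name, lift in {**self.planted_positive_drugs,
                           **self.planted_negative_drugs}.items():
            if lift <= 0:
                raise ConfigurationError(f"lift for {name!r} must be > 0")
        for name, lift in self.planted_positive_drugs.items():
            if lift < 1:
                raise ConfigurationError(f"positive lift for {name!r} must be >= 1")
        for name, lift in self.planted_negative_drugs.items():
            if lift >= 1:
                raise ConfigurationError(f"negative lift for {name!r} must be < 1")
        n_planted = len(self.planted_positive_drugs) + len(self.planted_negative_drugs)
        if n_planted > self.n_drugs:
            raise ConfigurationError("more planted drugs than n_drugs")


@dataclass
class SimulatedReports:
    """The four generated tables plus the ground truth behind them."""

    drug: pd.DataFrame
    reaction: pd.DataFrame
    demographic: pd.DataFrame
    therapy: pd.DataFrame
    ground_truth: pd.DataFrame          # drug_name, lift, planted, n_reports
    duplicated_ids: np.ndarray          # primary ids emitted twice
    inconsistent_ids: np.ndarray        # primary ids with a broken date triple
    n_unique_reports: int


def generate_report_tables(config: SimulationConfig) -> SimulatedReports:
    """Generate the four FAERS-shaped tables with planted signals."""
    rng_drug, rng_event, rng_dates, rng_dup, rng_conc = _spawn_rngs(config.seed, 5)
    n = config.n_reports

    planted = {**config.planted_positive_drugs, **config.planted_negative_drugs}
    drug_names = list(planted)
    drug_names += [f"DRUG_{i:04d}" for i in range(config.n_drugs - len(drug_names))]
    lifts = np.array([planted.get(name, 1.0) for name in drug_names])
    atc = [_ATC_CLASSES[i % len(_ATC_CLASSES)] + f"A{i % 9:02d}"
           for i in range(config.n_drugs)]

    # Heavy-tailed per-drug report shares.
    weights = rng_drug.lognormal(mean=0.0, sigma=config.report_count_sigma,
                                 size=config.n_drugs)
    weights /= weights.sum()
    drug_idx = rng_drug.choice(config.n_drugs, size=n, p=weights)

    # Target event: odds of a planted drug = lift x background odds.
    r = config.target_event_rate
    base_odds = r / (1.0 - r) if r < 1.0 else np.inf
    odds = lifts[drug_idx] * base_odds
    p_event = odds / (1.0 + odds)
    is_target = rng_event.random(n) < p_event

    # Therapy window and onset.  Valid rows satisfy start <= onset <= end;
    # inconsistent rows violate exactly one of the two inequalities.
    start = rng_dates.integers(0, _DATE_SPAN_DAYS, size=n)
    duration = rng_dates.integers(1, 365, size=n)
    end = start + duration
    onset = start + (rng_dates.random(n) * duration).astype(int)
    bad = rng_dates.random(n) < config.date_inconsistency_fraction
    which = rng_dates.random(n) < 0.5  # True: break start<=onset, else onset<=end
    offset = rng_dates.integers(1, 30, size=n)
    onset = np.where(bad & which, start - offset, onset)
    onset = np.where(bad & ~which, end + offset, onset)

    primaryid = np.arange(1, n + 1)
    names_arr = np.array(drug_names, dtype=object)
    atc_arr = np.array(atc, dtype=object)
    role = np.where(rng_drug.random(n) < 0.8, "PS", "SS")
    pt = np.where(
        is_target,
        TARGET_EVENT_TERM,
        np.array(_BACKGROUND_TERMS, dtype=object)[
            rng_event.integers(0, len(_BACKGROUND_TERMS), size=n)],
    )

    def _dt(days: np.ndarray) -> np.ndarray:
        return (_DATE_ORIGIN + days.astype("timedelta64[D]")).astype("datetime64[ns]")

    drug_tab = pd.DataFrame({
        "primaryid": primaryid,
        "drug_seq": 1,
        "drug_name": names_arr[drug_idx],
        "atc_code": atc_arr[drug_idx],
        "role_code": role,
    })
    reaction_tab = pd.DataFrame({"primaryid": primaryid, "pt": pt})
    demo_tab = pd.DataFrame({
        "primaryid": primaryid,
        "caseversion": 1,
        "event_dt": _dt(onset),
    })
    therapy_tab = pd.DataFrame({
        "primaryid": primaryid,
        "drug_seq": 1,
        "start_dt": _dt(start),
        "end_dt": _dt(end),
    })

    # Concomitant rows: extra Drug rows with role C/I that the suspect-drug
    # filter must remove (the event was generated from the suspect drug).
    n_conc = int(round(config.concomitant_fraction * n))
    if n_conc:
        conc_ids = rng_conc.choice(primaryid, size=n_conc, replace=False)
        conc_drug = rng_conc.integers(0, config.n_drugs, size=n_conc)
        conc = pd.DataFrame({
            "primaryid": conc_ids,
            "drug_seq": 2,
            "drug_name": names_arr[conc_drug],
            "atc_code": atc_arr[conc_drug],
            "role_code": np.where(rng_conc.random(n_conc) < 0.5, "C", "I"),
        })
        drug_tab = pd.concat([drug_tab, conc], ignore_index=True)

    # Duplicate submissions: exact copies; the Demographic copy carries an
    # incremented case version, mirroring quarterly resubmissions.
    dup_mask = rng_dup.random(n) < config.duplicate_fraction
    dup_ids = primaryid[dup_mask]
    if dup_ids.size:
        drug_tab = pd.concat(
            [drug_tab, drug_tab[drug_tab["primaryid"].isin(dup_ids)]],
            ignore_index=True)
        reaction_tab = pd.concat(
            [reaction_tab, reaction_tab[reaction_tab["primaryid"].isin(dup_ids)]],
            ignore_index=True)
        therapy_tab = pd.concat(
            [therapy_tab, therapy_tab[therapy_tab["primaryid"].isin(dup_ids)]],
            ignore_index=True)
        demo_dup = demo_tab[demo_tab["primaryid"].isin(dup_ids)].copy()
        demo_dup["caseversion"] = 2
        demo_tab = pd.concat([demo_tab, demo_dup], ignore_index=True)

    counts = pd.Series(drug_idx).value_counts().reindex(
        range(config.n_drugs), fill_value=0)
    truth = pd.DataFrame({
        "drug_name": drug_names,
        "lift": lifts,
        "planted": [name in planted for name in drug_names],
        "n_reports": counts.to_numpy(),
        "atc_code": atc,
    })

    return SimulatedReports(
        drug=drug_tab.reset_index(drop=True),
        reaction=reaction_tab.reset_index(drop=True),
        demographic=demo_tab.reset_index(drop=True),
        therapy=therapy_tab.reset_index(drop=True),
        ground_truth=truth,
        duplicated_ids=dup_ids,
        inconsistent_ids=primaryid[bad],
        n_unique_reports=n,
    )


# ---------------------------------------------------------------------------
# FAERS-dialect round trip
# ---------------------------------------------------------------------------

def write_faers_table(table: pd.DataFrame, path, dialect: str = "faers") -> None:
    """Write a table as '$'-separated FAERS quarterly text or plain CSV.

    Dates are serialized as the compact ``YYYYMMDD`` integers FAERS uses.
    """
    sep = "$" if dialect == "faers" else ","
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y%m%d")
    out.to_csv(path, sep=sep, index=False)


def read_faers_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_faers_table`, sniffing the dialect."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        sep = "$" if "$" in header else ","
        fh.seek(0)
        df = pd.read_csv(io.StringIO(fh.read()), sep=sep)
    for col in df.columns:
        if col.endswith("_dt"):
            df[col] = pd.to_datetime(df[col].astype("string"), format="%Y%m%d",
                                     errors="coerce")
    return df


# ---------------------------------------------------------------------------
# Descriptor-matrix simulation
# ---------------------------------------------------------------------------

#: Default informative feature: total polar surface area, whose positive
#: class sits higher with less spread than the negative class.
DEFAULT_INFORMATIVE = {"ASA_P": ((220.72, 84.95), (176.09, 193.00))}

#: Row-exclusion reasons mirroring manual curation of a drug list.
EXCLUSION_REASONS = (
    "mixture", "large_peptide", "biologic", "inorganic",
    "organometallic", "unresolved_name",
)


@dataclass
class DescriptorSimConfig:
    """Conditions for one synthetic drugs-by-descriptors matrix.

    ``informative_features`` maps descriptor name to
    ``((mean_pos, sd_pos), (mean_neg, sd_neg))``.  Values are censored at
    zero (negative draws clipped to 0 — surface areas cannot be negative,
    and a wide class distribution piles up at zero like apolar drugs do),
    which biases wide-spread class means upward; realized class means are
    therefore reported alongside the matrix.  Noise columns are standard
    normal; ``n_collinear_duplicates`` adds exact affine copies of existing
    columns and ``n_missing_columns`` adds noise columns with missing cells.
    """

    n_positive: int = 60
    n_negative: int = 108
    informative_features: dict[str, tuple[tuple[float, float],
                                          tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_INFORMATIVE))
    n_noise_features: int = 30
    n_collinear_duplicates: int = 2
    n_missing_columns: int = 2
    truncate_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ConfigurationError("class counts must be >= 0")
        for cnt in (self.n_noise_features, self.n_collinear_duplicates,
                    self.n_missing_columns):
            if cnt < 0:
                raise ConfigurationError("feature counts must be >= 0")
        for name, ((_, sd_p), (_, sd_n)) in self.informative_features.items():
            if sd_p <= 0 or sd_n <= 0:
                raise ConfigurationError(f"sd for {name!r} must be > 0")
        if self.n_collinear_duplicates and not (
                self.informative_features or self.n_noise_features):
            raise ConfigurationError(
                "collinear duplicates need at least one source column")


@dataclass
class SimulatedDescriptors:
    """Descriptor matrix plus the ground truth of its construction."""

    matrix: pd.DataFrame                 # drug_name, smiles, label, excl_*, features
    informative_columns: list[str]
    noise_columns: list[str]
    collinear_columns: dict[str, str]    # duplicate -> source
    missing_columns: list[str]
    realized_means: pd.DataFrame         # feature, class, realized mean/sd


def _censored_normal(rng: np.random.Generator, mean: float, sd: float,
                     size: int, censor: bool) -> np.ndarray:
    draw = rng.normal(mean, sd, size=size)
    return np.maximum(draw, 0.0) if censor else draw


def generate_descriptor_matrix(config: DescriptorSimConfig) -> SimulatedDescriptors:
    """Generate a labeled descriptor matrix with planted class structure."""
    rng_inf, rng_noise, rng_coll = _spawn_rngs(config.seed, 3)
    n_pos, n_neg = config.n_positive, config.n_negative
    n = n_pos + n_neg
    labels = np.array(["positive"] * n_pos + ["negative"] * n_neg)

    data: dict[str, np.ndarray] = {}
    realized = []
    for name, ((mu_p, sd_p), (mu_n, sd_n)) in config.informative_features.items():
        pos = _censored_normal(rng_inf, mu_p, sd_p, n_pos, config.truncate_at_zero)
        neg = _censored_normal(rng_inf, mu_n, sd_n, n_neg, config.truncate_at_zero)
        data[name] = np.concatenate([pos, neg])
        realized.append((name, "positive", pos.mean() if n_pos else np.nan,
                         pos.std(ddof=1) if n_pos > 1 else np.nan))
        realized.append((name, "negative", neg.mean() if n_neg else np.nan,
                         neg.std(ddof=1) if n_neg > 1 else np.nan))

    noise_cols = [f"noise_{i:03d}" for i in range(config.n_noise_features)]
    for col in noise_cols:
        data[col] = rng_noise.normal(0.0, 1.0, size=n)

    sources = list(data)
    collinear: dict[str, str] = {}
    for i in range(config.n_collinear_duplicates):
        src = sources[int(rng_coll.integers(0, len(sources)))]
        scale = float(rng_coll.uniform(0.5, 2.0))
        shift = float(rng_coll.normal(0.0, 1.0))
        col = f"dup_{i:02d}_of_{src}"
        data[col] = scale * data[src] + shift
        collinear[col] = src

    missing_cols = [f"miss_{i:02d}" for i in range(config.n_missing_columns)]
    for col in missing_cols:
        values = rng_noise.normal(0.0, 1.0, size=n)
        n_nan = max(1, int(round(0.05 * n)))
        values[rng_noise.choice(n, size=n_nan, replace=False)] = np.nan
        data[col] = values

    matrix = pd.DataFrame({
        "drug_name": [f"CMPD_{i:04d}" for i in range(n)],
        "smiles": ["CC"] * n,  # placeholder structures; descriptors are planted
        "label": labels,
    })
    for reason in EXCLUSION_REASONS:
        matrix[f"excl_{reason}"] = False
    for col, values in data.items():
        matrix[col] = values

    return SimulatedDescriptors(
        matrix=matrix,
        informative_columns=list(config.informative_features),
        noise_columns=noise_cols,
        collinear_columns=collinear,
        missing_columns=missing_cols,
        realized_means=pd.DataFrame(
            realized, columns=["feature", "class", "mean", "sd"]),
    )
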