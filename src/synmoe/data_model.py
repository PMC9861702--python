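"""Domain types, label construction and tabular I/O.

A cohort is three tables: a drug-descriptor table (one row per drug, 541
continuous chemical descriptors at full scale), a cell-line expression table
(one row per cell line, 927 landmark genes), and a combination table (drug
pair, cell line, five synergy scores, and the two binary labels).

Labels follow the study's construction: a combination is called synergistic
when its Loewe score strictly exceeds a threshold (default 5), and a drug
pair carries a positive drug-drug-interaction (DDI) label when its recorded
interaction category is adverse; pairs with a benign category or no record
are negative.  DDI labels attach to the unordered pair and are therefore
identical across every cell line of that pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGRESSION_TASKS = ("loewe", "bliss", "zip", "hsa", "s")
SYNERGY_TASK = "synergy"
DDI_TASK = "ddi"
CLASSIFICATION_TASKS = (SYNERGY_TASK, DDI_TASK)
ALL_TASKS = REGRESSION_TASKS + CLASSIFICATION_TASKS

DEFAULT_SYNERGY_THRESHOLD = 5.0


class ValidationError(ValueError):
    """Input data violates a documented contract."""


class LookupError_(KeyError):
    """An id does not resolve in the feature store."""


@dataclass(frozen=True)
class DDICategory:
    """One DrugBank-style interaction category."""
    name: str
    adverse: bool


# 18 interaction categories, 16 adverse, mirroring the curated category set's
# adverse/benign split.  Names are synthetic placeholders with the same
# semantics (pair-level pharmacological interaction types).
DEFAULT_DDI_CATEGORIES: tuple[DDICategory, ...] = tuple(
    [DDICategory(name, True) for name in (
        "increased_cardiotoxicity_risk", "increased_qt_prolongation",
        "increased_bleeding_risk", "increased_nephrotoxicity_risk",
        "increased_hepatotoxicity_risk", "increased_myelosuppression",
        "increased_hypotension_risk", "increased_serum_concentration",
        "decreased_renal_excretion", "increased_neurotoxicity_risk",
        "increased_gastrointestinal_toxicity", "increased_myopathy_risk",
        "increased_immunosuppression", "increased_sedation_risk",
        "decreased_therapeutic_efficacy", "increased_hyperkalemia_risk",
    )] + [
        DDICategory("improved_absorption", False),
        DDICategory("additive_benign_effect", False),
    ]
)

DDI_CATEGORY_INDEX = {c.name: c for c in DEFAULT_DDI_CATEGORIES}


@dataclass
class FeatureStore:
    """Keyed lookup of drug descriptor and cell-line expression vectors."""

    drug_features: dict[str, np.ndarray]
    cell_features: dict[str, np.ndarray]

    def __post_init__(self):
        for kind, table in (("drug", self.drug_features), ("cell", self.cell_features)):
            lengths = {v.shape[0] for v in table.values()}
            if len(lengths) > 1:
                raise ValidationError(f"{kind} vectors have mixed lengths: {sorted(lengths)}")
            for key, vec in table.items():
                if not np.all(np.isfinite(vec)):
                    raise ValidationError(f"non-finite values in {kind} vector {key!r}")

    @property
    def p_d(self) -> int:
        return next(iter(self.drug_features.values())).shape[0]

    @property
    def p_c(self) -> int:
        return next(iter(self.cell_features.values())).shape[0]

    def drug(self, drug_id: str) -> np.ndarray:
        try:
            return self.drug_features[drug_id]
        except KeyError:
            raise LookupError_(f"unknown drug id {drug_id!r}") from None

    def cell(self, cell_id: str) -> np.ndarray:
        try:
            return self.cell_features[cell_id]
        except KeyError:
            raise LookupError_(f"unknown cell line id {cell_id!r}") from None


@dataclass
class CombinationSample:
    """One (drug x, drug y, cell line) record with scores and labels."""

    drug_x: str
    drug_y: str
    cell_line: str
    scores: dict[str, float]
    synergy_label: int
    ddi_label: int

    def __post_init__(self):
        if self.drug_x == self.drug_y:
            raise ValidationError(f"drug_x == drug_y ({self.drug_x!r})")
        if self.synergy_label not in (0, 1) or self.ddi_label not in (0, 1):
            raise ValidationError("labels must be 0 or 1")

    @property
    def pair_key(self) -> tuple[str, str]:
        return tuple(sorted((self.drug_x, self.drug_y)))  # type: ignore[return-value]

    def swapped(self) -> "CombinationSample":
        return replace(self, drug_x=self.drug_y, drug_y=self.drug_x)


@dataclass
class Dataset:
    samples: list[CombinationSample]
    store: FeatureStore
    truth: object | None = field(default=None, repr=False)

    def __post_init__(self):
        for s in self.samples:
            self.store.drug(s.drug_x)
            self.store.drug(s.drug_y)
            self.store.cell(s.cell_line)

    def __len__(self) -> int:
        return len(self.samples)


# --------------------------------------------------------------------------
# label construction
# --------------------------------------------------------------------------

def assign_synergy_label(loewe: float, threshold: float = DEFAULT_SYNERGY_THRESHOLD) -> int:
    """1 iff the Loewe score strictly exceeds the threshold.

    A score exactly at the threshold is labeled 0, keeping the positive
    (synergistic) set conservative.
    """
    if not math.isfinite(loewe):
        raise ValidationError(f"non-finite Loewe score: {loewe}")
    return int(loewe > threshold)


def assign_ddi_label(category: DDICategory | str | None) -> int:
    """1 iff a recorded interaction category exists and is adverse.

    Benign categories and pairs with no record are both negative.
    """
    if category is None:
        return 0
    if isinstance(category, str):
        if category == "" or category.lower() in ("none", "nan"):
            return 0
        try:
            category = DDI_CATEGORY_INDEX[category]
        except KeyError:
            raise ValidationError(f"unknown DDI category {category!r}") from None
    return int(category.adverse)


def average_replicates(samples: list[CombinationSample],
                       threshold: float = DEFAULT_SYNERGY_THRESHOLD,
                       ) -> list[CombinationSample]:
    """Collapse replicate measurements of the same (unordered pair, cell line).

    Scores are averaged arithmetically; the synergy label is re-derived from
    the averaged Loewe score.  Replicates must agree on the DDI label (it is
    a pair-level property).  Output keeps the first-seen order and first-seen
    drug orientation of each group.
    """
    groups: dict[tuple, list[CombinationSample]] = {}
    order: list[tuple] = []
    for s in samples:
        key = s.pair_key + (s.cell_line,)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(s)
    out: list[CombinationSample] = []
    for key in order:
        group = groups[key]
        ddi_labels = {g.ddi_label for g in group}
        if len(ddi_labels) > 1:
            raise ValidationError(f"conflicting DDI labels for replicates of {key}")
        first = group[0]
        task_names = first.scores.keys()
        scores = {t: float(np.mean([g.scores[t] for g in group])) for t in task_names}
        out.append(CombinationSample(
            drug_x=first.drug_x, drug_y=first.drug_y, cell_line=first.cell_line,
            scores=scores,
            synergy_label=assign_synergy_label(scores["loewe"], threshold),
            ddi_label=first.ddi_label,
        ))
    return out


def drop_constant_features(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove zero-variance columns; returns (reduced matrix, kept indices)."""
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValidationError("empty feature matrix")
    kept = np.flatnonzero(np.ptp(matrix, axis=0) != 0)
    return matrix[:, kept], kept


def build_model_input(sample: CombinationSample, store: FeatureStore,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (dx, dy, cr) vectors; concatenation happens inside the experts."""
    return store.drug(sample.drug_x), store.drug(sample.drug_y), store.cell(sample.cell_line)


# --------------------------------------------------------------------------
# tabular I/O
# --------------------------------------------------------------------------

def _read_table(path, delimiter: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=delimiter)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed table {path}: {exc}") from None


def load_feature_table(path, kind: str = "drug", delimiter: str = ",",
                       ) -> dict[str, np.ndarray]:
    """Read an id + numeric-features table into an id -> vector map.

    First column is the id; every remaining column must be numeric.  Raises
    on duplicate ids and reports the offending row/column on parse failure.
    """
    if kind not in ("drug", "cell"):
        raise ValueError(f"kind must be 'drug' or 'cell', got {kind!r}")
    df = _read_table(path, delimiter)
    ids = df.iloc[:, 0].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate {kind} id(s): {sorted(set(dup))}")
    values = df.iloc[:, 1:].copy()
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() & values[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric value in column {col!r}, row {row}: {values[col].iloc[row]!r}")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValidationError(f"missing value in column {col!r}, row {row}")
        values[col] = numeric
    mat = values.to_numpy(dtype=np.float64)
    return {i: mat[k] for k, i in enumerate(ids)}


def write_feature_table(table: dict[str, np.ndarray], path, id_name: str = "id") -> None:
    df = pd.DataFrame.from_dict({k: v for k, v in table.items()}, orient="index")
    df.index.name = id_name
    df.columns = [f"f{j}" for j in range(df.shape[1])]
    df.to_csv(path)


def load_combination_table(path, delimiter: str = ",",
                           threshold: float = DEFAULT_SYNERGY_THRESHOLD,
                           ) -> list[CombinationSample]:
    """Read a combination table into samples.

    Expected columns: drug_x, drug_y, cell_line, the five score columns
    (loewe, bliss, zip, hsa, s), and either ddi_label (0/1) or ddi_category
    (text).  synergy_label, if absent, is derived from the Loewe score.
    """
    df = _read_table(path, delimiter)
    required = ["drug_x", "drug_y", "cell_line", *REGRESSION_TASKS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"combination table missing columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        scores = {t: float(row[t]) for t in REGRESSION_TASKS}
        if "ddi_label" in df.columns:
            ddi = int(row["ddi_label"])
        elif "ddi_category" in df.columns:
            cat = row["ddi_category"]
            ddi = assign_ddi_label(None if pd.isna(cat) else str(cat))
        else:
            raise ValidationError("need a ddi_label or ddi_category column")
        if "synergy_label" in df.columns:
            syn = int(row["synergy_label"])
        else:
            syn = assign_synergy_label(scores["loewe"], threshold)
        samples.append(CombinationSample(
            drug_x=str(row["drug_x"]), drug_y=str(row["drug_y"]),
            cell_line=str(row["cell_line"]), scores=scores,
            synergy_label=syn, ddi_label=ddi))
    return samples


def write_combination_table(samples: list[CombinationSample], path) -> None:
    rows = [{
        "drug_x": s.drug_x, "drug_y": s.drug_y, "cell_line": s.cell_line,
        **{t: s.scores[t] for t in REGRESSION_TASKS},
        "synergy_label": s.synergy_label, "ddi_label": s.ddi_label,
    } for s in samples]
    pd.DataFrame(rows).to_csv(path, index=False)
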