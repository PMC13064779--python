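"""Input containers for symptom-checklist studies.

Holds the four inputs the analyses consume: a persons x items binary matrix of
lifetime symptom endorsements (checklist style, 64 items by default), a map
assigning each item to one of five symptom domains, a persons x 10 ordinal
(0-4) severity-rating matrix, and a per-person lifetime-diagnosis flag.

All files are UTF-8 comma-separated text with a header row. Missing checklist
or severity entries are coded by an empty cell or ``NA`` and are kept as an
explicit missing marker (NaN internally): absence of an assessment is never
coerced to absence of a symptom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FLOAT_FMT

DOMAINS = (
    "doubt_checking",
    "contamination",
    "symmetry_ordering",
    "hoarding",
    "taboo",
)

#: default item count per domain; the three printed sizes are 16/15/18 and the
#: remaining 64 items split as contamination=13, hoarding=2 (hoarding has one
#: obsession and one compulsion item).
DEFAULT_DOMAIN_SIZES = {
    "doubt_checking": 16,
    "contamination": 13,
    "symmetry_ordering": 15,
    "hoarding": 2,
    "taboo": 18,
}

N_SEVERITY_ITEMS = 10
SEVERITY_ITEM_IDS = (
    "time_obs",
    "interference_obs",
    "distress_obs",
    "resistance_obs",
    "control_obs",
    "time_comp",
    "interference_comp",
    "distress_comp",
    "resistance_comp",
    "control_comp",
)

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class DatasetError(ValueError):
    """Raised for malformed or inconsistent study inputs."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ItemResponseMatrix:
    """Persons x items binary lifetime endorsements; NaN marks missing."""

    person_ids: list
    item_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_ids = [str(i) for i in self.item_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.person_ids), len(self.item_ids)):
            raise DatasetError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.person_ids)} persons x {len(self.item_ids)} items"
            )
        if len(set(self.person_ids)) != len(self.person_ids):
            dupes = _duplicates(self.person_ids)
            raise DatasetError(f"duplicate person ids: {dupes}")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise DatasetError(f"duplicate item ids: {_duplicates(self.item_ids)}")
        obs = self.values[~np.isnan(self.values)]
        bad = obs[(obs != 0.0) & (obs != 1.0)]
        if bad.size:
            raise DatasetError(
                f"non-binary checklist entries present (example value {bad[0]!r})"
            )

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def endorsement_rates(self) -> np.ndarray:
        """Per-item mean of observed entries (NaN for all-missing items)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def symptom_counts(self) -> np.ndarray:
        """Per-person count of endorsed (==1) observed symptoms."""
        return np.nansum(self.values == 1.0, axis=1).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.person_ids, columns=self.item_ids)

    def write(self, path) -> None:
        df = self.to_frame()
        out = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
        out.index.name = "person_id"
        out.to_csv(path)


@dataclass
class DomainMap:
    """Partition of checklist items into named symptom domains (testlets)."""

    mapping: dict  # item_id -> domain label
    strict: bool = True

    def __post_init__(self):
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}
        if not self.mapping:
            raise DatasetError("domain map is empty")
        labels = set(self.mapping.values())
        if self.strict:
            unknown = labels - set(DOMAINS)
            if unknown:
                raise DatasetError(f"unknown domain labels: {sorted(unknown)}")
            missing = set(DOMAINS) - labels
            if missing:
                raise DatasetError(
                    f"strict mode requires all 5 domains; missing {sorted(missing)}"
                )

    @property
    def item_ids(self) -> list:
        return list(self.mapping)

    @property
    def domains(self) -> list:
        """Domain labels in canonical order (strict) or first-seen order."""
        if self.strict:
            return [d for d in DOMAINS if d in set(self.mapping.values())]
        seen = []
        for d in self.mapping.values():
            if d not in seen:
                seen.append(d)
        return seen

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def items_in(self, domain: str) -> list:
        return [i for i, d in self.mapping.items() if d == domain]

    def counts(self) -> dict:
        return {d: len(self.items_in(d)) for d in self.domains}

    def domain_index(self, item_order: list) -> np.ndarray:
        """Integer domain index per item, following ``item_order``."""
        order = {d: k for k, d in enumerate(self.domains)}
        try:
            return np.array([order[self.mapping[str(i)]] for i in item_order])
        except KeyError as exc:
            raise DatasetError(f"item {exc} not present in domain map") from exc

    def write(self, path) -> None:
        pd.DataFrame(
            {"item_id": list(self.mapping), "domain": list(self.mapping.values())}
        ).to_csv(path, index=False)


@dataclass
class SeverityMatrix:
    """Persons x 10 clinician severity ratings in {0..4}; NaN = not administered."""

    person_ids: list
    item_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.person_ids = [str(p) for p in self.person_ids]
        self.item_ids = [str(i) for i in self.item_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.person_ids), len(self.item_ids)):
            raise DatasetError("severity matrix shape mismatch")
        if len(self.item_ids) != N_SEVERITY_ITEMS:
            raise DatasetError(
                f"severity scale has {N_SEVERITY_ITEMS} items, got {len(self.item_ids)}"
            )
        if len(set(self.person_ids)) != len(self.person_ids):
            raise DatasetError(f"duplicate person ids: {_duplicates(self.person_ids)}")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (
            np.any(obs != np.round(obs)) or obs.min() < 0 or obs.max() > 4
        ):
            raise DatasetError("severity entries must be integers in 0..4")

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.person_ids, columns=self.item_ids)

    def write(self, path) -> None:
        out = self.to_frame().map(lambda v: "" if np.isnan(v) else str(int(v)))
        out.index.name = "person_id"
        out.to_csv(path)


@dataclass
class AffectedFlags:
    """person_id -> lifetime-diagnosis boolean."""

    flags: dict

    def __post_init__(self):
        self.flags = {str(k): bool(v) for k, v in self.flags.items()}

    def __getitem__(self, pid) -> bool:
        return self.flags[str(pid)]

    def __contains__(self, pid) -> bool:
        return str(pid) in self.flags

    def vector(self, person_ids) -> np.ndarray:
        try:
            return np.array([self.flags[str(p)] for p in person_ids], dtype=bool)
        except KeyError as exc:
            raise DatasetError(f"diagnosis flag missing for person {exc}") from exc

    def write(self, path) -> None:
        pd.DataFrame(
            {
                "person_id": list(self.flags),
                "affected": [int(v) for v in self.flags.values()],
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers


def _duplicates(seq) -> list:
    seen, dup = set(), []
    for s in seq:
        if s in seen and s not in dup:
            dup.append(s)
        seen.add(s)
    return dup


def _parse_cell_matrix(path, allowed: set, kind: str) -> tuple[list, list, np.ndarray]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
    person_ids = [str(p) for p in df.index]
    item_ids = [str(c) for c in df.columns]
    if df.index.duplicated().any():
        raise DatasetError(
            f"duplicate person id(s) in {path}: "
            f"{sorted(set(df.index[df.index.duplicated()]))}"
        )
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, item in enumerate(item_ids):
        col = raw[:, j]
        for i, cell in enumerate(col):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                values[i, j] = np.nan
            elif cell in allowed:
                values[i, j] = float(cell)
            else:
                raise DatasetError(
                    f"malformed {kind} entry {cell!r} at row {person_ids[i]!r}, "
                    f"column {item!r} in {path}"
                )
    return person_ids, item_ids, values


def read_responses(path) -> ItemResponseMatrix:
    """Read a persons x items 0/1 checklist matrix from delimited text."""
    person_ids, item_ids, values = _parse_cell_matrix(path, {"0", "1"}, "checklist")
    return ItemResponseMatrix(person_ids, item_ids, values)


def read_severity(path) -> SeverityMatrix:
    """Read a persons x 10 ordinal (0-4) severity matrix from delimited text."""
    person_ids, item_ids, values = _parse_cell_matrix(
        path, {"0", "1", "2", "3", "4"}, "severity"
    )
    return SeverityMatrix(person_ids, item_ids, values)


def read_domain_map(path, strict: bool = True) -> DomainMap:
    """Read a two-column (item_id, domain) file into a DomainMap."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["item_id", "domain"]:
        raise DatasetError(
            f"domain map must have columns item_id,domain; got {list(df.columns)}"
        )
    if df["item_id"].duplicated().any():
        dup = sorted(set(df["item_id"][df["item_id"].duplicated()]))
        raise DatasetError(f"item(s) listed in more than one domain row: {dup}")
    return DomainMap(dict(zip(df["item_id"], df["domain"])), strict=strict)


def read_flags(path) -> AffectedFlags:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df["person_id"].duplicated().any():
        raise DatasetError("duplicate person ids in flags file")
    ok = {"0", "1", "True", "False", "true", "false"}
    bad = set(df["affected"]) - ok
    if bad:
        raise DatasetError(f"malformed affected flag value(s): {sorted(bad)}")
    truthy = {"1", "True", "true"}
    return AffectedFlags(
        {p: (v in truthy) for p, v in zip(df["person_id"], df["affected"])}
    )


def default_item_ids() -> list:
    return [f"item{k:02d}" for k in range(1, 65)]


def default_domain_map() -> DomainMap:
    """The packaged 64-item map: contiguous blocks per domain in canonical order."""
    ids = default_item_ids()
    mapping, pos = {}, 0
    for d in DOMAINS:
        for _ in range(DEFAULT_DOMAIN_SIZES[d]):
            mapping[ids[pos]] = d
            pos += 1
    return DomainMap(mapping)


# ---------------------------------------------------------------------------
# operations


def impute_zero_severity(
    sev: SeverityMatrix, resp: ItemResponseMatrix, flags: AffectedFlags
) -> tuple[SeverityMatrix, int]:
    """Assign all-zero severity rows to symptom-free undiagnosed persons.

    A person's not-administered severity row is replaced by ten zeros when the
    person (a) carries no lifetime diagnosis, (b) has a fully observed,
    all-zero checklist row, and (c) has no administered severity rating. All
    other rows are left untouched; in particular, diagnosed persons with
    missing ratings stay missing. Returns the new matrix and the number of
    imputed rows. Idempotent.
    """
    if sev.person_ids != resp.person_ids:
        raise DatasetError("severity and checklist person ids are misaligned")
    affected = flags.vector(sev.person_ids)
    fully_observed = resp.observed_mask().all(axis=1)
    no_symptoms = fully_observed & ~np.any(resp.values == 1.0, axis=1)
    not_administered = ~sev.observed_mask().any(axis=1)
    rows = (~affected) & no_symptoms & not_administered
    values = sev.values.copy()
    values[rows, :] = 0.0
    return (
        SeverityMatrix(list(sev.person_ids), list(sev.item_ids), values),
        int(rows.sum()),
    )


def symptom_pattern_summary(resp: ItemResponseMatrix) -> dict:
    """Summarize heterogeneity of lifetime response patterns.

    Returns the proportion of persons endorsing at least one symptom, the
    number of distinct patterns among symptomatic persons, the proportion of
    symptomatic persons whose full pattern is unique in the sample, and the
    most frequent symptomatic patterns with counts. Missing entries enter the
    pattern key as 'M' so patterns differing only in assessment coverage are
    not conflated.
    """
    n = resp.n_persons
    symptomatic = np.any(resp.values == 1.0, axis=1)
    keys = [
        "".join("M" if np.isnan(v) else str(int(v)) for v in row)
        for row in resp.values
    ]
    sym_keys = [k for k, s in zip(keys, symptomatic) if s]
    counts: dict = {}
    for k in sym_keys:
        counts[k] = counts.get(k, 0) + 1
    n_sym = len(sym_keys)
    n_unique = sum(1 for k in sym_keys if counts[k] == 1)
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
    return {
        "n_persons": n,
        "prop_symptomatic": (n_sym / n) if n else 0.0,
        "n_distinct_symptomatic_patterns": len(counts),
        "prop_unique_among_symptomatic": (n_unique / n_sym) if n_sym else 0.0,
        "top_patterns": top,
    }


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    info: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "errors": self.errors,
            "warnings": self.warnings,
            "info": self.info,
        }


def validate_dataset(
    resp: ItemResponseMatrix,
    dmap: DomainMap | None = None,
    sev: SeverityMatrix | None = None,
    flags: AffectedFlags | None = None,
) -> ValidationReport:
    """Cross-check the study inputs and summarize endorsement rates."""
    rep = ValidationReport()
    if dmap is not None:
        map_items = set(dmap.item_ids)
        mat_items = set(resp.item_ids)
        for missing in sorted(map_items - mat_items):
            rep.errors.append(f"item {missing!r} in domain map but not in matrix")
        for extra in sorted(mat_items - map_items):
            rep.errors.append(f"item {extra!r} in matrix but not in domain map")
        rep.info["domain_counts"] = dmap.counts()
    if sev is not None:
        if len(sev.item_ids) != N_SEVERITY_ITEMS:
            rep.errors.append(
                f"severity matrix has {len(sev.item_ids)} columns, "
                f"expected {N_SEVERITY_ITEMS}"
            )
        if sev.person_ids != resp.person_ids:
            rep.errors.append("severity person ids misaligned with checklist")
    if flags is not None:
        missing = [p for p in resp.person_ids if p not in flags]
        if missing:
            rep.errors.append(
                f"diagnosis flags missing for {len(missing)} person(s), "
                f"e.g. {missing[:3]}"
            )
    rates = resp.endorsement_rates()
    rep.info["endorsement_rates"] = {
        i: (None if np.isnan(r) else round(float(r), 6))
        for i, r in zip(resp.item_ids, rates)
    }
    degenerate = [
        i for i, r in zip(resp.item_ids, rates) if not np.isnan(r) and r in (0.0, 1.0)
    ]
    if degenerate:
        rep.warnings.append(f"items with no response variation: {degenerate}")
    frac_missing = float(np.isnan(resp.values).mean())
    rep.info["checklist_missing_fraction"] = round(frac_missing, 6)
    if frac_missing > 0.2:
        rep.warnings.append("more than 20% of checklist entries are missing")
    return rep
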