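"""Data model for the reverse-time-course progeny assays.

The ICR (intersister/intrachromatid repair), IH (interhomolog) and brood
viability assays all share the same experimental skeleton: a heat shock (or
irradiation) hits oocytes at every stage of meiotic prophase I at once, and
because nuclei move through the gonad at a known rate, progeny laid within a
given interval post treatment derive from oocytes that were at a known stage
when the DNA damage was induced.  Scoring progeny in timepoint windows
therefore converts laying time into meiotic stage.

The four canonical windows tile 10-58 hours post heat shock.  Progeny laid
22-58 h derive from oocytes that still had the homolog available as a repair
template (the "interhomolog window"); progeny laid 10-22 h derive from late
pachytene/diplotene oocytes that did not (the "non-interhomolog window").
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Window",
    "WINDOWS",
    "PHENOTYPE_CLASSES",
    "ProgenyRecord",
    "SCERecord",
    "BroodRecord",
    "ValidationError",
    "assign_window",
    "is_interhomolog",
    "load_progeny_table",
    "write_progeny_table",
    "load_sce_table",
    "load_brood_table",
    "write_brood_table",
    "aggregate_counts",
]


class Window(enum.Enum):
    """Timepoint window, labelled by its half-open interval [start, end) in
    hours post heat shock."""

    T10_22 = (10.0, 22.0)
    T22_34 = (22.0, 34.0)
    T34_46 = (34.0, 46.0)
    T46_58 = (46.0, 58.0)

    @property
    def start_hr(self) -> float:
        return self.value[0]

    @property
    def end_hr(self) -> float:
        return self.value[1]

    @property
    def label(self) -> str:
        return f"{self.value[0]:g}-{self.value[1]:g}"


WINDOWS: tuple[Window, ...] = tuple(Window)

#: Mutually exclusive phenotype classes scored per plate.  "undetermined
#: recombinants" (unsequenced GFP+ / non-Unc progeny) are first-class: they
#: stay in plate totals but are excluded from recombinant-class denominators.
PHENOTYPE_CLASSES: tuple[str, ...] = (
    "NCO_recombinant",
    "CO_recombinant",
    "mutant",
    "undetermined_recombinant",
    "nonrecombinant",
    "dead_egg",
    "unfertilized",
)

ASSAY_SPAN = (10.0, 58.0)


def assign_window(hours_post_heat_shock: float) -> Window:
    """Map a laying time (hours post heat shock) to its timepoint window.

    Windows are half-open [start, end): a transfer at hour 22 starts the next
    window, matching the transfer-at-22/34/46, discard-at-58 protocol.

    Raises ``ValueError`` outside [10, 58).
    """
    h = float(hours_post_heat_shock)
    if not (h == h and h >= 0):  # NaN or negative
        raise ValueError("hours post heat shock must be a finite non-negative real")
    if not (ASSAY_SPAN[0] <= h < ASSAY_SPAN[1]):
        raise ValueError(
            f"{h} hr is outside the assay span [{ASSAY_SPAN[0]:g}, {ASSAY_SPAN[1]:g}) hr"
        )
    for w in WINDOWS:
        if w.start_hr <= h < w.end_hr:
            return w
    raise AssertionError("windows tile the assay span")  # pragma: no cover


def is_interhomolog(window: Window) -> bool:
    """True for windows inside the interhomolog window (22-58 hr post heat
    shock), False for the non-interhomolog window (10-22 hr)."""
    return window.start_hr >= 22.0


def _parse_window(text: str) -> Window:
    s = str(text).strip()
    for w in WINDOWS:
        if s in (w.name, w.label):
            return w
    raise ValueError(f"unknown timepoint window {text!r}")


@dataclasses.dataclass(frozen=True)
class ProgenyRecord:
    """Per-plate, per-window phenotype-class counts for the ICR/IH assays.

    ``parent_id`` identifies the plate; for assay variants run with three
    hermaphrodites per plate it is still the plate that is the atomic unit.
    """

    genotype: str
    replicate: str
    parent_id: str
    window: Window
    class_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for cls, count in self.class_counts.items():
            if cls not in PHENOTYPE_CLASSES:
                raise ValueError(f"unknown phenotype class {cls!r}")
            if int(count) < 0:
                raise ValueError(f"negative count for class {cls!r}: {count}")

    @property
    def total(self) -> int:
        return int(sum(self.class_counts.values()))


@dataclasses.dataclass(frozen=True)
class SCERecord:
    """Scorable diakinesis chromatid pairs with / without a sister chromatid
    exchange, per image."""

    genotype: str
    image_id: str
    sce_pairs: int
    scorable_pairs: int

    def __post_init__(self) -> None:
        if not (0 <= self.sce_pairs <= self.scorable_pairs):
            raise ValueError(
                f"need 0 <= sce_pairs <= scorable_pairs, got "
                f"{self.sce_pairs}/{self.scorable_pairs}"
            )


@dataclasses.dataclass(frozen=True)
class BroodRecord:
    """One hermaphrodite's brood at one timepoint window and radiation dose.

    Brood size is hatched + dead eggs; unfertilized oocytes are recorded but
    never enter the brood size, so viability = hatched / (hatched + dead).
    Brood windows are free-form labels ("10-22", "22-46", ...) because the
    viability protocol transfers at 10/22/46 h rather than the four canonical
    ICR transfer points.
    """

    genotype: str
    mated: bool
    window: str
    dose_rads: int
    hatched: int
    dead_eggs: int
    unfertilized: int = 0

    def __post_init__(self) -> None:
        for name in ("hatched", "dead_eggs", "unfertilized"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"negative {name}")

    @property
    def brood_size(self) -> int:
        return self.hatched + self.dead_eggs

    @property
    def viability(self) -> float | None:
        """Hatched / brood size; None for a zero brood (undefined)."""
        if self.brood_size == 0:
            return None
        return self.hatched / self.brood_size


class ValidationError(ValueError):
    """Raised by table loaders; carries one message per offending row."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


_PROGENY_SCHEMA = {
    "genotype": "genotype",
    "replicate": "replicate",
    "parent_id": "parent_id",
    "window": "window",
    **{cls: cls for cls in PHENOTYPE_CLASSES},
}


def _read_table(path) -> pd.DataFrame:
    # header sniffing: tab if the header line contains one, else comma
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_progeny_table(path, schema: Mapping[str, str] | None = None) -> list[ProgenyRecord]:
    """Load a delimited progeny-count table into validated records.

    ``schema`` maps logical names (genotype, replicate, parent_id, window and
    one entry per phenotype class) to the file's column names.  Malformed rows
    are reported together, with line numbers, in a ``ValidationError``.
    """
    schema = dict(_PROGENY_SCHEMA if schema is None else schema)
    df = _read_table(path)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {', '.join(missing)}"])
    records: list[ProgenyRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            counts = {}
            for cls in PHENOTYPE_CLASSES:
                raw = row[schema[cls]]
                n = int(raw)
                if n < 0:
                    raise ValueError(f"negative count {n} for {cls}")
                counts[cls] = n
            records.append(
                ProgenyRecord(
                    genotype=row[schema["genotype"]],
                    replicate=row[schema["replicate"]],
                    parent_id=row[schema["parent_id"]],
                    window=_parse_window(row[schema["window"]]),
                    class_counts=counts,
                )
            )
        except (ValueError, TypeError) as err:
            problems.append(f"line {line}: {err}")
    if problems:
        raise ValidationError(problems)
    return records


def write_progeny_table(records: Iterable[ProgenyRecord], path, sep: str = "\t") -> None:
    rows = [
        {
            "genotype": r.genotype,
            "replicate": r.replicate,
            "parent_id": r.parent_id,
            "window": r.window.label,
            **{cls: r.class_counts.get(cls, 0) for cls in PHENOTYPE_CLASSES},
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["genotype", "replicate", "parent_id", "window",
                                *PHENOTYPE_CLASSES]).to_csv(path, sep=sep, index=False)


def load_sce_table(path) -> list[SCERecord]:
    """Load a table of per-image scorable chromatid pairs with/without SCEs."""
    df = _read_table(path)
    missing = [c for c in ("genotype", "image_id", "sce_pairs", "scorable_pairs")
               if c not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {', '.join(missing)}"])
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            records.append(
                SCERecord(row["genotype"], row["image_id"],
                          int(row["sce_pairs"]), int(row["scorable_pairs"]))
            )
        except (ValueError, TypeError) as err:
            problems.append(f"line {idx + 2}: {err}")
    if problems:
        raise ValidationError(problems)
    return records


_BROOD_COLUMNS = ("genotype", "mated", "window", "dose_rads",
                  "hatched", "dead_eggs", "unfertilized")


def load_brood_table(path) -> list[BroodRecord]:
    df = _read_table(path)
    missing = [c for c in _BROOD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing columns: {', '.join(missing)}"])
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            records.append(
                BroodRecord(
                    genotype=row["genotype"],
                    mated=str(row["mated"]).strip().lower() in ("1", "true", "yes"),
                    window=str(row["window"]),
                    dose_rads=int(row["dose_rads"]),
                    hatched=int(row["hatched"]),
                    dead_eggs=int(row["dead_eggs"]),
                    unfertilized=int(row["unfertilized"]),
                )
            )
        except (ValueError, TypeError) as err:
            problems.append(f"line {idx + 2}: {err}")
    if problems:
        raise ValidationError(problems)
    return records


def write_brood_table(records: Iterable[BroodRecord], path, sep: str = "\t") -> None:
    rows = [
        {"genotype": r.genotype, "mated": str(r.mated).lower(), "window": r.window,
         "dose_rads": r.dose_rads, "hatched": r.hatched,
         "dead_eggs": r.dead_eggs, "unfertilized": r.unfertilized}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_BROOD_COLUMNS)).to_csv(path, sep=sep, index=False)


_GROUP_KEYS = ("genotype", "replicate", "parent_id", "window")


def aggregate_counts(
    records: Sequence[ProgenyRecord],
    by: Sequence[str] = ("genotype", "window"),
) -> pd.DataFrame:
    """Sum phenotype-class counts within groups.

    ``by`` is any subset of {genotype, replicate, parent_id, window}.  The
    grand total over all groups equals the sum over input records
    (conservation), for every grouping.
    """
    if not records:
        raise ValueError("no records to aggregate")
    unknown = [k for k in by if k not in _GROUP_KEYS]
    if unknown:
        raise ValueError(f"unknown grouping keys: {unknown}; valid: {_GROUP_KEYS}")
    rows = []
    for r in records:
        row = {
            "genotype": r.genotype,
            "replicate": r.replicate,
            "parent_id": r.parent_id,
            "window": r.window.label,
        }
        row.update({cls: r.class_counts.get(cls, 0) for cls in PHENOTYPE_CLASSES})
        rows.append(row)
    df = pd.DataFrame(rows)
    out = df.groupby(list(by), as_index=False, sort=True)[list(PHENOTYPE_CLASSES)].sum()
    out["recombinant_total"] = (
        out["NCO_recombinant"] + out["CO_recombinant"]
        + out["mutant"] + out["undetermined_recombinant"]
    )
    return out
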