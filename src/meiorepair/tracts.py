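"""Conversion-tract scoring and mutation-signature analysis.

The ICR assay locus carries a ladder of polymorphisms 12-567 bp 3' of the
Mos1 excision site.  Sequencing a recombinant scores each ladder position as
converted (copied from the repair template), unconverted, heteroduplex
(unresolved mismatched dsDNA, two peaks at the polymorphism), or unreadable.

Tract extent is measured on the ladder: the *minimum* tract spans the most
proximal to the most distal converted polymorphism (a single converted site
counts as 1 bp), and the *maximum* tract extends to the flanking unconverted
polymorphisms.  Noncrossover tracts are "short" when the only converted site
is the most proximal polymorphism at 12 bp; crossover tracts are "short" when
the minimum tract is <= 198 bp (the wild-type median crossover tract length).

Mutagenic repair products are scored for the signatures of theta-mediated end
joining (TMEJ): small (<50 bp) deletions flanked by junction microhomology,
or templated insertions.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import pandas as pd

from .assay import Window, _parse_window
from .freqstats import BinomialEstimate, fisher_exact_two_sided, wilson_ci

__all__ = [
    "CONVERTED", "UNCONVERTED", "HETERODUPLEX", "UNREADABLE",
    "DEFAULT_LADDER",
    "PolymorphismLadder",
    "ConversionTract",
    "TractLengths",
    "MutationEvent",
    "MutationSignature",
    "ShortTractSummary",
    "tract_lengths",
    "classify_nco",
    "classify_co",
    "has_heteroduplex",
    "junction_microhomology",
    "classify_mutation",
    "tract_summary",
    "load_tract_table",
    "write_tract_table",
]

CONVERTED = "converted"
UNCONVERTED = "unconverted"
HETERODUPLEX = "heteroduplex"
UNREADABLE = "unreadable"
_CALLS = (CONVERTED, UNCONVERTED, HETERODUPLEX, UNREADABLE)
_CALL_CODES = {"1": CONVERTED, "0": UNCONVERTED, "H": HETERODUPLEX, "N": UNREADABLE}
_CODE_OF = {v: k for k, v in _CALL_CODES.items()}

SHORT_CO_THRESHOLD_BP = 198


@dataclasses.dataclass(frozen=True)
class PolymorphismLadder:
    """Ordered bp offsets of the scored polymorphisms, 3' of the Mos1
    excision site (position 0).

    Only the endpoints (12 and 567 bp) are fixed by the assay design; the
    default interior positions here are a synthetic but representative set.
    Classification depends only on position 12 and the 198 bp threshold.
    """

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        p = self.positions
        if not p or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("ladder positions must be strictly increasing and nonempty")
        if p[0] <= 0:
            raise ValueError("ladder positions are bp offsets > 0")

    def __len__(self) -> int:
        return len(self.positions)


DEFAULT_LADDER = PolymorphismLadder((12, 77, 142, 209, 284, 352, 424, 495, 567))


@dataclasses.dataclass(frozen=True)
class ConversionTract:
    """Per-position calls for one sequenced recombinant."""

    recombinant_class: str  # "NCO" | "CO"
    window: Window
    calls: tuple[str, ...]
    tract_id: str = ""
    ambiguous: bool = False  # two distinguishable repair products: excluded

    def __post_init__(self) -> None:
        if self.recombinant_class not in ("NCO", "CO"):
            raise ValueError("recombinant_class must be 'NCO' or 'CO'")
        bad = [c for c in self.calls if c not in _CALLS]
        if bad:
            raise ValueError(f"unknown calls: {sorted(set(bad))}")


@dataclasses.dataclass(frozen=True)
class TractLengths:
    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_bp <= self.max_bp):
            raise ValueError("need 1 <= min_bp <= max_bp")


def _converted_idx(t: ConversionTract) -> list[int]:
    # heteroduplex counts as converted for tract extent and classification:
    # heteroduplex points are plotted inside tract spans
    return [i for i, c in enumerate(t.calls) if c in (CONVERTED, HETERODUPLEX)]


def tract_lengths(t: ConversionTract, ladder: PolymorphismLadder = DEFAULT_LADDER) -> TractLengths:
    """Minimum and maximum conversion tract lengths in bp.

    min_bp = (most distal converted - most proximal converted) + 1, so a
    single converted site yields 1 bp.  max_bp extends symmetrically to the
    nearest flanking *unconverted* polymorphism on each side (or to position
    0 proximally / one past the ladder end distally when there is none);
    unreadable positions are non-informative and never bound a tract.
    """
    if len(t.calls) != len(ladder):
        raise ValueError("calls must align 1:1 with ladder positions")
    conv = _converted_idx(t)
    if not conv:
        raise ValueError("no converted positions: not a scorable tract")
    pos = ladder.positions
    lo, hi = conv[0], conv[-1]
    min_bp = pos[hi] - pos[lo] + 1
    left_unconv = [pos[i] for i in range(lo) if t.calls[i] == UNCONVERTED]
    right_unconv = [pos[i] for i in range(hi + 1, len(pos)) if t.calls[i] == UNCONVERTED]
    left_bound = left_unconv[-1] if left_unconv else 0
    right_bound = right_unconv[0] if right_unconv else pos[-1] + 1
    return TractLengths(min_bp=min_bp, max_bp=right_bound - left_bound - 1)


def classify_nco(t: ConversionTract, ladder: PolymorphismLadder = DEFAULT_LADDER) -> str:
    """'short' iff the only converted/heteroduplex site is the most proximal
    ladder position (12 bp); otherwise 'long'."""
    if t.recombinant_class != "NCO":
        raise ValueError(f"classify_nco on a {t.recombinant_class} tract")
    if len(t.calls) != len(ladder):
        raise ValueError("calls must align 1:1 with ladder positions")
    conv = _converted_idx(t)
    if not conv:
        raise ValueError("no converted positions: not a scorable tract")
    return "short" if conv == [0] else "long"


def classify_co(t: ConversionTract, ladder: PolymorphismLadder = DEFAULT_LADDER) -> str:
    """'short' iff the minimum tract length is <= 198 bp (inclusive, the
    wild-type median crossover tract)."""
    if t.recombinant_class != "CO":
        raise ValueError(f"classify_co on a {t.recombinant_class} tract")
    return "short" if tract_lengths(t, ladder).min_bp <= SHORT_CO_THRESHOLD_BP else "long"


def has_heteroduplex(t: ConversionTract) -> bool:
    """True iff any ladder position was called heteroduplex."""
    if all(c == UNREADABLE for c in t.calls):
        warnings.warn("all positions unreadable: tract carries no information",
                      stacklevel=2)
    return any(c == HETERODUPLEX for c in t.calls)


def junction_microhomology(ref_seq: str, deletion: tuple[int, int]) -> int:
    """Microhomology length at a deletion junction.

    Returns the largest m >= 0 with ``ref_seq[s-m:s] == ref_seq[e-m:e]``:
    identical sequence abuts both junction sides, so the deletion breakpoint
    is ambiguous over m bases.  An empty deletion has no junction and scores 0.
    """
    s, e = deletion
    n = len(ref_seq)
    if not (0 <= s <= e <= n):
        raise ValueError(f"deletion [{s}, {e}) out of bounds for length-{n} reference")
    if s == e:
        return 0
    m = 0
    while m < min(s, e) and ref_seq[s - m - 1] == ref_seq[e - m - 1]:
        m += 1
    return m


@dataclasses.dataclass(frozen=True)
class MutationEvent:
    """A mutagenic repair product at the excision site: a deletion interval
    [s, e) in 0-based reference coordinates (possibly empty) plus an optional
    insertion."""

    ref_seq: str
    deletion: tuple[int, int]
    insertion_seq: str = ""
    templated: bool = False  # insertion matches nearby reference sequence

    def __post_init__(self) -> None:
        s, e = self.deletion
        if not (0 <= s <= e <= len(self.ref_seq)):
            raise ValueError("deletion interval out of bounds")


@dataclasses.dataclass(frozen=True)
class MutationSignature:
    size_bp: int
    mh_len: int
    templated_insertion: bool
    tmej_like: bool


TMEJ_DELETION_MAX_BP = 50


def classify_mutation(ev: MutationEvent) -> MutationSignature:
    """Score a mutation for TMEJ signatures.

    tmej_like iff the deletion is small (<50 bp) and either the junction
    shows microhomology (>= 1 complementary nucleotide on both ends) or the
    insertion is templated from nearby sequence.
    """
    s, e = ev.deletion
    mh = junction_microhomology(ev.ref_seq, ev.deletion)
    size = (e - s) + len(ev.insertion_seq)
    tmej = (e - s) < TMEJ_DELETION_MAX_BP and (mh >= 1 or ev.templated)
    return MutationSignature(size_bp=size, mh_len=mh,
                             templated_insertion=ev.templated, tmej_like=tmej)


@dataclasses.dataclass(frozen=True)
class ShortTractSummary:
    short: int
    total: int
    short_frac: BinomialEstimate
    p_vs_reference: float


def _short_long_counts(tracts: Sequence[ConversionTract], cls: str,
                       interhomolog: bool,
                       ladder: PolymorphismLadder) -> tuple[int, int]:
    from .assay import is_interhomolog
    classify = classify_nco if cls == "NCO" else classify_co
    short = total = 0
    for t in tracts:
        if t.ambiguous or t.recombinant_class != cls:
            continue
        if is_interhomolog(t.window) != interhomolog:
            continue
        total += 1
        short += classify(t, ladder) == "short"
    return short, total


def tract_summary(tracts: Sequence[ConversionTract], cls: str,
                  window_group: str,
                  reference: Sequence[ConversionTract],
                  ladder: PolymorphismLadder = DEFAULT_LADDER,
                  conf: float = 0.95) -> ShortTractSummary:
    """Short-tract fraction with Wilson CI and a two-sided Fisher p against a
    reference genotype's short/long counts.

    ``cls`` is "NCO" or "CO"; ``window_group`` is "IH" (22-58 hr) or "nonIH"
    (10-22 hr).  Tracts flagged ambiguous are excluded.
    """
    if cls not in ("NCO", "CO"):
        raise ValueError("cls must be 'NCO' or 'CO'")
    if window_group not in ("IH", "nonIH"):
        raise ValueError("window_group must be 'IH' or 'nonIH'")
    ih = window_group == "IH"
    k, n = _short_long_counts(tracts, cls, ih, ladder)
    kr, nr = _short_long_counts(reference, cls, ih, ladder)
    if n == 0 or nr == 0:
        raise ValueError("empty tract collection for the requested class/window")
    return ShortTractSummary(
        short=k, total=n,
        short_frac=wilson_ci(k, n, conf),
        p_vs_reference=fisher_exact_two_sided([[k, n - k], [kr, nr - kr]]),
    )


def load_tract_table(path, ladder: PolymorphismLadder = DEFAULT_LADDER) -> list[ConversionTract]:
    """Load a delimited tract table: one row per recombinant, columns
    tract_id, recombinant_class, window, then one column per ladder position
    (named by its bp offset) with calls coded 1/0/H/N, plus an optional
    ``ambiguous`` column."""
    from .assay import _read_table

    df = _read_table(path)
    pos_cols = [str(p) for p in ladder.positions]
    missing = [c for c in ("tract_id", "recombinant_class", "window", *pos_cols)
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    tracts = []
    for _, row in df.iterrows():
        calls = tuple(_CALL_CODES[str(row[c]).strip()] for c in pos_cols)
        tracts.append(ConversionTract(
            recombinant_class=str(row["recombinant_class"]).strip(),
            window=_parse_window(row["window"]),
            calls=calls,
            tract_id=str(row["tract_id"]),
            ambiguous=(str(row.get("ambiguous", "false")).strip().lower()
                       in ("1", "true", "yes")),
        ))
    return tracts


def write_tract_table(tracts: Iterable[ConversionTract], path,
                      ladder: PolymorphismLadder = DEFAULT_LADDER,
                      sep: str = "\t") -> None:
    rows = []
    for t in tracts:
        row = {"tract_id": t.tract_id, "recombinant_class": t.recombinant_class,
               "window": t.window.label, "ambiguous": str(t.ambiguous).lower()}
        row.update({str(p): _CODE_OF[c] for p, c in zip(ladder.positions, t.calls)})
        rows.append(row)
    cols = ["tract_id", "recombinant_class", "window", "ambiguous",
            *[str(p) for p in ladder.positions]]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
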