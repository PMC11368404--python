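"""Seeded synthetic-data generators.

Each generator emulates the shape and statistical structure of one of the
study's figure-level source-data tables, so every pipeline stage is testable
without any download: multinomial progeny-class counts per plate and window,
tract-call matrices over a polymorphism ladder, beta-binomial brood
viabilities with group-level (phi, lam), stage-dependent Poisson focus counts
along the gonad axis, and planted-microhomology deletion junctions.

Every generator is a pure function of (seed, its parameters).  Each one draws
from its own named pseudo-random stream derived from (seed, generator name),
so adding a generator never perturbs the others' outputs.
"""

from __future__ import annotations

import zlib
from collections.abc import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay import PHENOTYPE_CLASSES, WINDOWS, Window
from .rad51 import DEFAULT_SPAN, GermlineLandmarks
from .tracts import DEFAULT_LADDER, PolymorphismLadder

__all__ = [
    "gen_progeny",
    "gen_tracts",
    "gen_brood",
    "gen_germline",
    "gen_junctions",
    "DEFAULT_CLASS_RATES",
]


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named stream: independent of every other generator's stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


#: Plausible per-window phenotype-class rates for a wild-type-like ICR assay.
#: The published tables print only recombinant totals, so these rates are
#: synthetic defaults: rare recombinants among a large brood, a slight excess
#: of noncrossovers over crossovers, and a small dead-egg/unfertilized load.
DEFAULT_CLASS_RATES: dict[Window, dict[str, float]] = {
    w: {
        "NCO_recombinant": 0.006,
        "CO_recombinant": 0.002,
        "mutant": 0.0002,
        "undetermined_recombinant": 0.0008,
        "nonrecombinant": 0.951,
        "dead_egg": 0.025,
        "unfertilized": 0.015,
    }
    for w in WINDOWS
}


def gen_progeny(rates: Mapping[Window, Mapping[str, float]] | None = None,
                n_parents: int = 20, mean_brood: float = 60.0,
                seed: int = 0, genotype: str = "synthetic",
                replicate: str = "r1") -> pd.DataFrame:
    """Multinomial progeny-class counts per parent plate and window.

    Per parent per window: brood ~ Poisson(mean_brood per window), then class
    counts ~ Multinomial(brood, rates[window]).  Rates must sum to 1 per
    window (tolerance 1e-9).
    """
    rates = DEFAULT_CLASS_RATES if rates is None else rates
    for w, r in rates.items():
        total = sum(r.get(cls, 0.0) for cls in PHENOTYPE_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities for {w} sum to {total}, not 1")
    rng = _rng(seed, "progeny")
    rows = []
    for parent in range(n_parents):
        for w in sorted(rates, key=lambda w: w.start_hr):
            brood = rng.poisson(mean_brood)
            probs = [rates[w].get(cls, 0.0) for cls in PHENOTYPE_CLASSES]
            counts = rng.multinomial(brood, probs)
            rows.append({
                "genotype": genotype, "replicate": replicate,
                "parent_id": f"p{parent:03d}", "window": w.label,
                **dict(zip(PHENOTYPE_CLASSES, (int(c) for c in counts))),
            })
    return pd.DataFrame(rows)


def gen_tracts(ladder: PolymorphismLadder = DEFAULT_LADDER,
               class_mix: Mapping[str, float] | None = None,
               tract_len_dist: Callable[[np.random.Generator], float] | None = None,
               het_rate: float = 0.05, n: int = 50, seed: int = 0,
               ih_prob: float = 0.75) -> pd.DataFrame:
    """Tract-call matrices for ``n`` attempted DSB repair events.

    Each event draws a recombinant class from ``class_mix`` (default 70% NCO),
    a window (interhomolog with probability ``ih_prob``), and a true tract
    interval (0, L] anchored at the excision site with L from
    ``tract_len_dist`` (default: exponential with mean 120 bp, floored at
    1 bp).  Ladder positions inside the tract are converted; each converted
    call flips to heteroduplex with ``het_rate``.  Events whose tract covers
    no ladder position are not recombinants and are excluded, so the returned
    table may hold fewer than ``n`` rows.
    """
    class_mix = {"NCO": 0.7, "CO": 0.3} if class_mix is None else dict(class_mix)
    if tract_len_dist is None:
        def tract_len_dist(rng):  # noqa: ANN001
            return max(1.0, rng.exponential(120.0))
    rng = _rng(seed, "tracts")
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    ih_windows = [w for w in WINDOWS if w.start_hr >= 22.0]
    rows = []
    for i in range(n):
        cls = classes[rng.choice(len(classes), p=probs)]
        if rng.random() < ih_prob:
            window = ih_windows[rng.integers(len(ih_windows))]
        else:
            window = Window.T10_22
        length = float(tract_len_dist(rng))
        calls = []
        for p in ladder.positions:
            if p <= length:
                calls.append("H" if rng.random() < het_rate else "1")
            else:
                calls.append("0")
        if "1" not in calls and "H" not in calls:
            continue  # covered no polymorphism: scored nonrecombinant
        rows.append({"tract_id": f"t{i:04d}", "recombinant_class": cls,
                     "window": window.label, "ambiguous": "false",
                     **dict(zip((str(p) for p in ladder.positions), calls))})
    cols = ["tract_id", "recombinant_class", "window", "ambiguous",
            *[str(p) for p in ladder.positions]]
    return pd.DataFrame(rows, columns=cols)


def gen_brood(groups: Mapping[tuple, tuple[float, float, float, int]],
              seed: int = 0, mated: bool = False) -> pd.DataFrame:
    """Beta-binomial brood records.

    ``groups`` maps (genotype, window, dose_rads) -> (phi, lam, mean_brood,
    n_herm).  Per hermaphrodite: brood ~ Poisson(mean_brood),
    p ~ Beta(lam*phi, lam*(1-phi)), hatched ~ Binomial(brood, p) — the
    model's own generative process.  The study design is n_herm = 15 broods
    per genotype x condition.
    """
    rng = _rng(seed, "brood")
    rows = []
    for key in sorted(groups):
        phi, lam, mean_brood, n_herm = groups[key]
        if not (0.0 < phi < 1.0) or lam <= 0:
            raise ValueError(f"invalid (phi, lam) for group {key}")
        genotype, window, dose = key
        for _ in range(int(n_herm)):
            brood = int(rng.poisson(mean_brood))
            p = rng.beta(lam * phi, lam * (1.0 - phi))
            hatched = int(rng.binomial(brood, p))
            rows.append({"genotype": genotype, "mated": str(mated).lower(),
                         "window": window, "dose_rads": int(dose),
                         "hatched": hatched, "dead_eggs": brood - hatched,
                         "unfertilized": int(rng.poisson(2.0))})
    return pd.DataFrame(rows, columns=["genotype", "mated", "window", "dose_rads",
                                       "hatched", "dead_eggs", "unfertilized"])


def gen_germline(n_nuclei: int = 200,
                 stage_rate_fn: Callable[[np.ndarray], np.ndarray] | None = None,
                 seed: int = 0, germline_id: str = "g1",
                 landmarks: GermlineLandmarks | None = None,
                 span: tuple[float, float] = DEFAULT_SPAN) -> pd.DataFrame:
    """Per-nucleus focus counts along a synthetic germline.

    Nuclei are placed uniformly on the normalized span (-0.25, 1];
    foci ~ Poisson(stage_rate_fn(position)) (default: constant rate 2).
    If ``landmarks`` are given, raw axis positions are back-computed through
    the inverse of the pachytene normalization.
    """
    if stage_rate_fn is None:
        def stage_rate_fn(pos):  # noqa: ANN001
            return np.full_like(pos, 2.0)
    rng = _rng(seed, "germline")
    lo, hi = span
    pos = hi - rng.random(n_nuclei) * (hi - lo)  # uniform on (lo, hi]
    pos = np.sort(pos)
    rates = np.asarray(stage_rate_fn(pos), dtype=float)
    if np.any(rates < 0):
        raise ValueError("stage_rate_fn returned a negative Poisson rate")
    foci = rng.poisson(rates)
    df = pd.DataFrame({"germline_id": germline_id,
                       "norm_position": pos, "foci": foci})
    if landmarks is not None:
        span_len = landmarks.pachytene_end - landmarks.tz_end
        df.insert(1, "raw_position", landmarks.tz_end + pos * span_len)
    return df


_BASES = np.array(list("ACGT"))


def gen_junctions(ref_len: int = 60, del_size: int = 10, mh_len: int = 2,
                  n: int = 100, seed: int = 0) -> pd.DataFrame:
    """Deletion junctions with exactly the requested microhomology, planted.

    Each event is a random sequence with a deletion [s, e) of ``del_size`` bp
    constructed so the junction microhomology equals ``mh_len`` exactly
    (flanks forced equal for m = mh_len and unequal at m + 1), then verified
    against the literal maximal-m definition before emission.
    """
    from .tracts import junction_microhomology

    if mh_len < 0 or del_size < 0:
        raise ValueError("mh_len and del_size must be non-negative")
    if mh_len + del_size + 2 > ref_len:
        raise ValueError("infeasible geometry: mh_len + del_size + 2 > ref_len")
    if del_size == 0 and mh_len > 0:
        raise ValueError("an empty deletion has no junction: mh_len must be 0")
    rng = _rng(seed, "junctions")
    rows = []
    for i in range(n):
        for _ in range(10_000):  # construct-and-verify; deterministic per seed
            seq = rng.choice(_BASES, size=ref_len)
            s = int(rng.integers(mh_len + 1, ref_len - del_size + 1))
            e = s + del_size
            if del_size > 0:
                # plant: left flank tail == deleted-segment tail for mh_len bases
                for m in range(1, mh_len + 1):
                    seq[e - m] = seq[s - m]
                # break the match at mh_len + 1 on the left-flank side
                if mh_len + 1 <= min(s, e):
                    pool = [b for b in "ACGT" if b != seq[e - mh_len - 1]]
                    seq[s - mh_len - 1] = pool[rng.integers(3)]
            ref = "".join(seq)
            if junction_microhomology(ref, (s, e)) == mh_len:
                rows.append({"event_id": f"j{i:04d}", "ref_seq": ref,
                             "s": s, "e": e, "insertion_seq": "",
                             "planted_mh": mh_len})
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct the requested junction")
    return pd.DataFrame(rows, columns=["event_id", "ref_seq", "s", "e",
                                       "insertion_seq", "planted_mh"])
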