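"""Position weight matrices: construction, log-odds scanning, and
null-calibrated hit thresholds.

Log-odds are natural-log (nats) throughout. Hit thresholds are calibrated
against the PWM's null score distribution under the background model: for
motif lengths up to 10 the null is computed exactly by enumerating the
per-position score convolution; longer motifs fall back to Monte-Carlo
sampling. The threshold is the smallest score whose null tail probability
does not exceed the requested rate, and the realised (achievable) tail
probability is reported alongside it because scores are discrete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in index space


def encode(seq: str) -> np.ndarray:
    """ACGT string -> int array (A=0 C=1 G=2 T=3); other letters -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class Pwm:
    """Per-position base probabilities with a background model."""

    probs: np.ndarray  # (L, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.25
    name: str = "motif"

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", np.asarray(self.background, float))
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM must be (L, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if (probs <= 0).any():
            raise ValueError("PWM probabilities must be positive (use a pseudocount)")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_odds(self) -> np.ndarray:
        """(L, 5) log(p/bg) in nats; column 4 (ambiguous base) is -inf."""
        lo = np.log(self.probs / self.background)
        return np.hstack([lo, np.full((self.length, 1), -np.inf)])

    @cached_property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            probs=self.probs[::-1, _COMPLEMENT],
            background=self.background,
            pseudocount=self.pseudocount,
            name=self.name + "_rc",
        )

    # -- scanning -----------------------------------------------------------

    def scan(self, seq_ints: np.ndarray) -> np.ndarray:
        """Log-odds score at every start position of the forward strand."""
        n = len(seq_ints) - self.length + 1
        if n <= 0:
            return np.empty(0)
        lo = self.log_odds
        scores = np.zeros(n)
        for i in range(self.length):
            scores += lo[i, seq_ints[i : i + n]]
        return scores

    # -- null calibration ---------------------------------------------------

    @cached_property
    def _null_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted unique scores desc, tail probability P(S >= score))."""
        if self.length <= 10:
            vals = np.zeros(1)
            probs = np.ones(1)
            lo = self.log_odds[:, :4]
            for i in range(self.length):
                vals = (vals[:, None] + lo[i][None, :]).ravel()
                probs = (probs[:, None] * self.background[None, :]).ravel()
        else:  # Monte-Carlo fallback for long motifs
            rng = np.random.default_rng(0)
            draws = rng.choice(4, size=(200_000, self.length), p=self.background)
            vals = self.log_odds[np.arange(self.length), draws].sum(axis=1)
            probs = np.full(len(vals), 1.0 / len(vals))
        order = np.argsort(vals)[::-1]
        vals, probs = vals[order], probs[order]
        uniq, start = np.unique(-vals, return_index=True)
        tail = np.cumsum(probs)
        # tail prob at each unique score = P(S >= score)
        ends = np.append(start[1:], len(vals)) - 1
        return -uniq, tail[ends]

    def score_threshold(self, tail_prob: float = 0.001) -> tuple[float, float]:
        """Smallest score with null tail probability <= ``tail_prob``.

        Returns ``(threshold, realised_tail_prob)``; the realised tail can be
        below the nominal rate because the score distribution is discrete.
        """
        scores, tails = self._null_distribution
        ok = tails <= tail_prob
        if not ok.any():
            raise ValueError(f"no achievable threshold at tail_prob={tail_prob}")
        i = np.where(ok)[0][-1]  # scores sorted descending; last ok = smallest
        return float(scores[i]), float(tails[i])

    def best_hit(
        self, seq_ints: np.ndarray, center: int, window: int
    ) -> tuple[int, str, float] | None:
        """Best-scoring site whose midpoint lies within ±window of center.

        ``seq_ints`` is the encoded chromosome; ``center`` an absolute bp.
        Returns (offset of site midpoint from center, strand, score), with
        ties broken by smaller \\|offset\\|, then plus strand, then leftmost.
        Does not apply any threshold.
        """
        L = self.length
        mid = L // 2
        lo_start = center - window - mid
        hi_start = center + window - mid  # inclusive start bound
        lo_start = max(lo_start, 0)
        hi_start = min(hi_start, len(seq_ints) - L)
        if hi_start < lo_start:
            return None
        segment = seq_ints[lo_start : hi_start + L]
        offsets = np.arange(lo_start, hi_start + 1) + mid - center
        fwd = self.scan(segment)
        rev = self.reverse_complement().scan(segment)
        off2 = np.concatenate([offsets, offsets])
        scores = np.concatenate([fwd, rev])
        strand_code = np.concatenate(
            [np.zeros(len(fwd), int), np.ones(len(rev), int)]
        )
        # lexsort keys, least significant first: leftmost, plus strand,
        # smaller |offset|, then highest score
        i = np.lexsort((off2, strand_code, np.abs(off2), -scores))[0]
        return int(off2[i]), "+" if strand_code[i] == 0 else "-", float(scores[i])


def pwm_from_sites(sites, pseudocount: float = 0.25, background=None, name="motif") -> Pwm:
    """Build a PWM from aligned equal-length sites.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount);
    N bases are distributed to the background composition.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("cannot build a PWM from an empty site list")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("all sites must have equal length")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, float)
    counts = np.zeros((L, 4))
    for site in sites:
        for i, b in enumerate(site.upper()):
            if b in _BASE_INDEX:
                counts[i, _BASE_INDEX[b]] += 1.0
            elif b == "N":
                counts[i] += background
            else:
                raise ValueError(f"invalid base {b!r} in site {site!r}")
    n = len(sites)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return Pwm(probs=probs, background=background, pseudocount=pseudocount, name=name)


def pwm_from_consensus(
    consensus: str, strength: float = 0.97, background=None, name="motif"
) -> Pwm:
    """A sharp PWM putting ``strength`` probability on each consensus base."""
    cons = encode(consensus)
    if (cons > 3).any():
        raise ValueError("consensus must be ACGT only")
    L = len(cons)
    probs = np.full((L, 4), (1 - strength) / 3)
    probs[np.arange(L), cons] = strength
    if background is None:
        background = np.full(4, 0.25)
    return Pwm(probs=probs, background=np.asarray(background, float), name=name)


def read_pwm(path, name=None, **kwargs) -> Pwm:
    """Read a position probability matrix: one row per position, columns
    A C G T, whitespace-separated; '#' comments allowed."""
    mat = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, float_precision="round_trip"
    ).to_numpy(float)
    return Pwm(probs=mat, name=name or str(path), **kwargs)


def write_pwm(pwm: Pwm, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: A C G T\n")
        for row in pwm.probs:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
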