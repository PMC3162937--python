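"""Per-helix gap-free profile models, scoring and threshold calibration.

Because helix windows are aligned without gaps, each helix is modelled as a
position-specific log-odds profile over the 20-letter alphabet; aligning a
profile to a sequence is an exhaustive scan of every window of the profile's
length, keeping the maximum-score offset.  Thresholds separating real helices
from background are calibrated on artificial sequences drawn i.i.d. from the
helix's seed amino-acid composition: the cutoff is set so that 95% of the
artificial sequences fail it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bw import HELIX_SLICES, TM_BOUNDARIES, helix_length
from .msa import ALPHABET, SequenceRecord, TMAlignment, encode_sequence

__all__ = [
    "HelixProfile",
    "HelixHit",
    "CalibratedThresholds",
    "build_profile",
    "build_all_profiles",
    "gapfree_align",
    "calibrate_thresholds",
]

N_AA = len(ALPHABET)


@dataclass(frozen=True)
class HelixProfile:
    """Gap-free position-specific log-odds profile of one helix window.

    ``weights[j, a] = log(((count_a + k * bg_a) / (N + k)) / bg_a)`` where
    ``k`` is the pseudocount mass and ``bg`` the background amino-acid
    frequencies estimated from the whole seed alignment.
    """

    helix: int
    length: int
    weights: np.ndarray          # (length, 20) float64, finite everywhere
    background: np.ndarray       # (20,) frequencies, sums to 1
    pseudocount: float
    seed_composition: np.ndarray = field(repr=False, default=None)  # (20,) helix aa freqs

    def __post_init__(self) -> None:
        if self.weights.shape != (self.length, N_AA):
            raise ValueError("profile weight matrix has wrong shape")
        if not np.isfinite(self.weights).all():
            raise ValueError("profile weights must be finite")

    def consensus(self) -> str:
        return "".join(ALPHABET[a] for a in self.weights.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())


@dataclass(frozen=True)
class HelixHit:
    """Best gap-free placement of one helix profile in a sequence."""

    helix: int
    offset: int          # 0-based start, window is [offset, offset + length)
    score: float
    passed: bool = False


@dataclass(frozen=True)
class CalibratedThresholds:
    """Per-helix score cutoffs from the artificial-sequence calibration."""

    cutoffs: dict[int, float]
    n_artificial: int
    artificial_length: int
    rng_seed: int
    quantile: float = 0.95

    def passes(self, helix: int, score: float) -> bool:
        return score > self.cutoffs[helix]


def build_profile(
    seed: TMAlignment,
    helix: int,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> HelixProfile:
    """Build the log-odds profile of one helix from the seed alignment.

    The background is the amino-acid frequency over every column of the seed
    (all 171 columns), shared by the seven helices so that scores are on a
    common scale.
    """
    if helix not in TM_BOUNDARIES:
        raise ValueError(f"helix must be in 1..7, got {helix}")
    if len(seed) == 0:
        raise ValueError("empty seed alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    mat = seed.matrix
    standard = mat < N_AA
    if background is None:
        counts = np.bincount(mat[standard].ravel(), minlength=N_AA).astype(float)
        if counts.sum() == 0:
            raise ValueError("seed contains no standard amino acids")
        background = counts / counts.sum()
    background = np.asarray(background, dtype=float)

    lo, hi = HELIX_SLICES[helix]
    length = hi - lo
    weights = np.empty((length, N_AA))
    seg = mat[:, lo:hi]
    seg_ok = standard[:, lo:hi]
    comp = np.bincount(seg[seg_ok].ravel(), minlength=N_AA).astype(float)
    comp = comp / comp.sum() if comp.sum() else np.full(N_AA, 1.0 / N_AA)
    for j in range(length):
        col = seg[:, j][seg_ok[:, j]]
        counts = np.bincount(col, minlength=N_AA).astype(float)
        n = counts.sum()
        p = (counts + pseudocount * background) / (n + pseudocount)
        weights[j] = np.log(p / background)
    return HelixProfile(helix, length, weights, background, pseudocount, comp)


def build_all_profiles(
    seed: TMAlignment, pseudocount: float = 1.0
) -> dict[int, HelixProfile]:
    """Profiles for all 7 helices, sharing one seed-wide background."""
    mat = seed.matrix
    ok = mat < N_AA
    counts = np.bincount(mat[ok].ravel(), minlength=N_AA).astype(float)
    bg = counts / counts.sum()
    return {h: build_profile(seed, h, pseudocount, bg) for h in sorted(TM_BOUNDARIES)}


def _window_scores(profile: HelixProfile, codes: np.ndarray) -> np.ndarray:
    """Score of every admissible window start; ambiguity symbols score 0."""
    L = profile.length
    n = codes.shape[0]
    if n < L:
        return np.empty(0)
    # pad the weight matrix with a zero column so ambiguity codes are neutral
    w = np.concatenate([profile.weights, np.zeros((L, 1))], axis=1)
    safe = np.minimum(codes, N_AA)
    windows = np.lib.stride_tricks.sliding_window_view(safe, L)  # (n-L+1, L)
    return w[np.arange(L), windows].sum(axis=1)


def gapfree_align(
    profile: HelixProfile,
    seq: SequenceRecord | str,
    search_range: tuple[int, int] | None = None,
) -> HelixHit:
    """Best gap-free placement of ``profile`` in ``seq``.

    ``search_range`` is a half-open interval ``[a, b)`` of the sequence; the
    window must lie entirely inside it.  Ties are broken toward the smallest
    offset.  Raises :class:`ValueError` when no window fits.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    codes = encode_sequence(s)
    a, b = (0, len(s)) if search_range is None else search_range
    a, b = max(a, 0), min(b, len(s))
    if b - a < profile.length:
        raise ValueError(
            f"no gap-free placement: helix {profile.helix} needs "
            f"{profile.length} residues but search range [{a}, {b}) "
            f"holds {max(b - a, 0)}"
        )
    scores = _window_scores(profile, codes[a:b])
    best = int(np.argmax(scores))  # argmax returns the first maximum: tie rule
    return HelixHit(profile.helix, a + best, float(scores[best]))


def calibrate_thresholds(
    profiles: dict[int, HelixProfile],
    n_artificial: int = 10_000,
    rng_seed: int = 0,
    artificial_length: int = 350,
    quantile: float = 0.95,
) -> CalibratedThresholds:
    """Set per-helix cutoffs so 95% of artificial sequences fail them.

    For each helix, ``n_artificial`` sequences of ``artificial_length``
    residues are drawn i.i.d. from the helix's seed amino-acid composition and
    scored with the same max-over-windows search used for real sequences.  The
    cutoff is the empirical ``quantile`` of those scores under the
    lower-interpolation convention: exactly ``ceil(quantile * n)`` artificial
    scores fall at or below the cutoff, and passing requires a score strictly
    above it.
    """
    if n_artificial < 100:
        raise ValueError("n_artificial must be at least 100")
    rng = np.random.default_rng(rng_seed)
    cutoffs: dict[int, float] = {}
    for helix in sorted(profiles):
        prof = profiles[helix]
        comp = prof.seed_composition
        if comp is None:
            comp = np.full(N_AA, 1.0 / N_AA)
        if np.count_nonzero(comp) == 1:
            warnings.warn(
                f"helix {helix}: degenerate single-letter seed composition; "
                "calibration cutoff is still defined",
                stacklevel=2,
            )
        draws = rng.choice(N_AA, size=(n_artificial, artificial_length), p=comp)
        scores = np.empty(n_artificial)
        for i in range(n_artificial):
            scores[i] = _window_scores(prof, draws[i].astype(np.int8)).max()
        order = np.sort(scores)
        k = math.ceil(quantile * n_artificial)  # lower-interpolation quantile
        cutoffs[helix] = float(order[k - 1])
    return CalibratedThresholds(
        cutoffs, n_artificial, artificial_length, rng_seed, quantile
    )
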