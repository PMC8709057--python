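"""Brain Hacking Recognizer (BHR): channel-mixing integrity verification.

Transmitter and receiver share a seeded PRNG. At iteration *i* both derive
the same ordered 4-tuple of distinct channel indexes ``(a, b, c, d)``. The
transmitter replaces those channels of the outgoing N-channel frame with an
algebraic mixture; the receiver, knowing the tuple, reconstructs the
original signals and cross-checks the redundant encoding. An attacker who
injects a frame without knowing the tuple (N·(N−1)·(N−2)·(N−3) ordered
choices; 24,024 at N = 14) almost surely breaks the redundancy and is
detected.

Mixing (with offsets ``u_a = s_a + C1``, ``u_b = s_b + C2``,
``v_c = s_c + C2``; C1 − C2 > 2R keeps every denominator away from zero
for signals bounded by ±R):

====  ======================================
slot  content
====  ======================================
b     ``s_b`` (raw reference)
c     ``x = u_a·u_b / (u_a + u_b)``
d     ``y = u_a·u_b / (u_a − u_b)``
a     ``z = u_a·v_c / (u_a + v_c)``
====  ======================================

Verification uses the harmonic identity ``2xy/(x+y) = u_b``: the receiver
recomputes ``û_b`` from slots c and d and compares it against the raw
reference in slot b. On a match, ``û_a`` follows from ``1/û_a = 1/x −
1/û_b`` and ``v̂_c`` from ``1/v̂_c = 1/z − 1/û_a``. Because the harmonic
mean is symmetric in (x, y), the ``û_b`` comparison alone cannot see every
wrong disposition (e.g. a c/d swap, or a tuple differing only in role a);
the receiver therefore also requires every reconstructed signal to lie
inside the physical amplitude bound ±R, which those cases violate by
construction (reconstructions land thousands of µV off). Any division
guard tripped by tampered data likewise yields a ``compromised`` verdict,
never a numeric fault.

The original signal on channel d is sacrificed (three signals travel in
four slots, one of which is redundancy); the receiver fills it per policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import DataError

__all__ = [
    "PRNGState",
    "ChannelTuple",
    "BHRConfig",
    "MixedFrame",
    "ReconstructionResult",
    "n_arrangements",
    "tuple_from_index",
    "tuple_for",
    "next_tuple",
    "encode",
    "forge",
    "decode_verify",
    "inhibit",
]


class ChannelTuple(NamedTuple):
    """Ordered roles (a, b, c, d): four distinct channel indexes."""

    a: int
    b: int
    c: int
    d: int


@dataclass
class PRNGState:
    """Synchronized tuple scheduler: deterministic per (seed, iteration).

    A software stand-in for a hardware-derived shared seed; both link ends
    construct the same state and step it in lockstep.
    """

    seed: int
    iteration: int = 0
    kind: str = "philox"


@dataclass(frozen=True)
class BHRConfig:
    """Numerical-safety envelope of the mixing algebra.

    ``offset_c1 − offset_c2 > 2·amplitude_bound`` keeps the ``u_a − u_b``
    denominator strictly positive; ``offset_c2 > amplitude_bound`` keeps
    every offset signal strictly positive.
    """

    n_channels: int = 14
    offset_c1: float = 2000.0  # µV, role-a offset C1
    offset_c2: float = 1000.0  # µV, role-b/c offset C2
    amplitude_bound: float = 100.0  # µV, R
    tau: float = 1e-6  # relative verification threshold
    d_fill_policy: str = "zeros"  # {"zeros", "reference_copy"}
    #: absolute slack (µV) on the |signal| <= R plausibility check
    bound_slack: float = 1e-3

    def __post_init__(self):
        if self.n_channels < 4:
            raise ValueError("BHR needs at least 4 channels")
        if not self.offset_c1 - self.offset_c2 > 2 * self.amplitude_bound:
            raise ValueError("require C1 - C2 > 2R")
        if not self.offset_c2 > self.amplitude_bound:
            raise ValueError("require C2 > R")
        if self.d_fill_policy not in ("zeros", "reference_copy"):
            raise ValueError(f"unknown d_fill_policy {self.d_fill_policy!r}")


@dataclass
class MixedFrame:
    """An N-channel frame after BHR encoding (plus its iteration tag)."""

    data: np.ndarray
    iteration: int = 0

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class ReconstructionResult:
    """Receiver-side outcome for one frame."""

    verdict: str  # {"legitimate", "compromised"}
    epsilon: float
    a_hat: np.ndarray | None = None
    b_hat: np.ndarray | None = None
    c_hat: np.ndarray | None = None
    frame: np.ndarray | None = None  # reconstructed N-channel frame

    @property
    def compromised(self) -> bool:
        return self.verdict == "compromised"


def n_arrangements(n: int) -> int:
    """Number of ordered 4-tuples of distinct channels: N(N−1)(N−2)(N−3)."""
    if n < 4:
        raise ValueError("need at least 4 channels")
    return n * (n - 1) * (n - 2) * (n - 3)


def tuple_from_index(idx: int, n: int) -> ChannelTuple:
    """Unrank ``idx`` in [0, N(N−1)(N−2)(N−3)) to an ordered distinct 4-tuple."""
    m = n_arrangements(n)
    if not 0 <= idx < m:
        raise ValueError("tuple index out of range")
    avail = list(range(n))
    picks = []
    bases = [(n - 1) * (n - 2) * (n - 3), (n - 2) * (n - 3), (n - 3), 1]
    for b in bases:
        digit, idx = divmod(idx, b)
        picks.append(avail.pop(digit))
    return ChannelTuple(*picks)


def tuple_for(seed: int, iteration: int, n: int) -> ChannelTuple:
    """The tuple both ends derive at (seed, iteration): stateless lookup.

    Uses a counter-based generator keyed by ``seed`` with the iteration in
    the counter, so any iteration is addressable in O(1) on either end.
    """
    m = n_arrangements(n)
    g = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, iteration]))
    return tuple_from_index(int(g.integers(m)), n)


def next_tuple(prng: PRNGState, n: int) -> ChannelTuple:
    """Draw the tuple for the current iteration and advance the state."""
    t = tuple_for(prng.seed, prng.iteration, n)
    prng.iteration += 1
    return t


def encode(frame: np.ndarray, t: ChannelTuple, cfg: BHRConfig = BHRConfig()) -> MixedFrame:
    """Transmitter-side mixing of channels (a, b, c, d); others passthrough.

    Every input sample must satisfy ``|s| <= R`` (the generator's soft clip
    and winsorizing-style acquisition limits guarantee this for legitimate
    streams).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 1:
        frame = frame[None, :].copy()
    if frame.shape[0] != cfg.n_channels:
        raise ValueError(
            f"frame has {frame.shape[0]} channels, config says {cfg.n_channels}"
        )
    if len(set(t)) != 4 or any(not 0 <= i < cfg.n_channels for i in t):
        raise ValueError(f"invalid channel tuple {t} for N={cfg.n_channels}")
    r = cfg.amplitude_bound
    if np.max(np.abs(frame)) > r + cfg.bound_slack:
        raise DataError(f"frame amplitude exceeds the ±{r} µV bound")

    u_a = frame[t.a] + cfg.offset_c1
    u_b = frame[t.b] + cfg.offset_c2
    v_c = frame[t.c] + cfg.offset_c2
    # denominator bound guaranteed by C1 - C2 > 2R
    assert np.min(np.abs(u_a - u_b)) >= cfg.offset_c1 - cfg.offset_c2 - 2 * r - 1e-9

    out = frame.copy()
    out[t.c] = u_a * u_b / (u_a + u_b)  # x
    out[t.d] = u_a * u_b / (u_a - u_b)  # y
    out[t.a] = u_a * v_c / (u_a + v_c)  # z
    # slot b keeps the raw reference s_b
    return MixedFrame(data=out)


def forge(fake_frame: np.ndarray, guessed: ChannelTuple, cfg: BHRConfig = BHRConfig()) -> MixedFrame:
    """Attacker-side encoder: same mixing, under the attacker's guessed tuple."""
    return encode(fake_frame, guessed, cfg)


def decode_verify(
    mixed: MixedFrame, t: ChannelTuple, cfg: BHRConfig = BHRConfig()
) -> ReconstructionResult:
    """Receiver-side verification and reconstruction.

    Computes ``û_b = 2xy/(x+y)`` from slots c and d, compares ``b̂ = û_b −
    C2`` against the raw reference in slot b (relative deviation
    ``epsilon``), then reconstructs â and ĉ. The verdict is
    ``compromised`` when ``epsilon > tau``, when any division guard trips,
    or when a reconstructed signal leaves the physical ±R range; only a
    fully verified frame is emitted.
    """
    data = np.asarray(mixed.data, dtype=np.float64)
    s_b = data[t.b]
    x = data[t.c]
    y = data[t.d]
    z = data[t.a]
    r = cfg.amplitude_bound
    guard = 1e-9

    def _bad(epsilon=np.inf):
        return ReconstructionResult(verdict="compromised", epsilon=float(epsilon))

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom_xy = x + y
        if np.min(np.abs(denom_xy)) < guard:
            return _bad()
        u_b_hat = 2.0 * x * y / denom_xy
        b_hat = u_b_hat - cfg.offset_c2
        epsilon = float(np.max(np.abs(b_hat - s_b) / (np.abs(s_b) + 1.0)))
        if not np.isfinite(epsilon) or epsilon > cfg.tau:
            return _bad(epsilon if np.isfinite(epsilon) else np.inf)

        denom_a = u_b_hat - x  # 1/û_a = 1/x − 1/û_b
        if np.min(np.abs(denom_a)) < guard:
            return _bad(epsilon)
        u_a_hat = x * u_b_hat / denom_a
        a_hat = u_a_hat - cfg.offset_c1

        denom_c = u_a_hat - z  # 1/v̂_c = 1/z − 1/û_a
        if np.min(np.abs(denom_c)) < guard:
            return _bad(epsilon)
        v_c_hat = z * u_a_hat / denom_c
        c_hat = v_c_hat - cfg.offset_c2

    for sig in (a_hat, b_hat, c_hat):
        if not np.all(np.isfinite(sig)) or np.max(np.abs(sig)) > r + cfg.bound_slack:
            return _bad(epsilon)

    frame = data.copy()
    frame[t.a] = a_hat
    frame[t.b] = s_b
    frame[t.c] = c_hat
    if cfg.d_fill_policy == "zeros":
        frame[t.d] = 0.0
    else:  # reference_copy
        frame[t.d] = s_b
    return ReconstructionResult(
        verdict="legitimate",
        epsilon=epsilon,
        a_hat=a_hat,
        b_hat=b_hat,
        c_hat=c_hat,
        frame=frame,
    )


def inhibit(verdict: str, classifier_label: str):
    """Attack inhibition: a compromised trial is forced to non-P300.

    Returns ``(final_label, warning)``. A false negative only stalls a
    speller; a false positive under attack would actuate it, so forcing the
    negative class is the safe counteraction.
    """
    if verdict == "compromised":
        return "nonP300", True
    return classifier_label, False
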