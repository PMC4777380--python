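"""Synthetic Poisson spike-train generation and statistics.

All stochastic inputs used by the simulations are produced here: homogeneous
Poisson spike trains for the uncorrelated excitatory and inhibitory inputs,
and groups of pairwise-correlated Poisson trains built by thinning a common
higher-rate parent train (each child keeps every parent spike independently
with probability ``c``, giving every child the nominal rate and every pair a
zero-lag count correlation of exactly ``c``).

Units: spike times and durations in milliseconds, rates in Hz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import as_seedseq

__all__ = [
    "SpikeTrain",
    "InputEnsemble",
    "generate_homogeneous_poisson",
    "generate_correlated_group",
    "measure_pairwise_correlation",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered set of spike times on one channel.

    Parameters
    ----------
    times : np.ndarray
        Strictly increasing spike times in ms, all within ``[0, duration)``.
    duration : float
        Total observation span in ms.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self):
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Empirical rate in Hz."""
        return 1000.0 * self.n_spikes / self.duration

    def binned_counts(self, bin_width: float) -> np.ndarray:
        """Spike counts in contiguous bins of ``bin_width`` ms."""
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins = int(self.duration // bin_width)
        counts = np.bincount(
            (self.times[self.times < n_bins * bin_width] / bin_width).astype(np.int64),
            minlength=n_bins,
        )
        return counts[:n_bins]


def generate_homogeneous_poisson(
    rate: float, duration: float, seed=None
) -> SpikeTrain:
    """Generate a homogeneous Poisson spike train.

    Parameters
    ----------
    rate : float
        Rate in Hz (>= 0).
    duration : float
        Span in ms (> 0).
    seed : int, np.random.Generator or np.random.SeedSequence, optional
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration / 1000.0)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    # ties have probability zero in continuous time; drop them defensively
    if times.size > 1:
        keep = np.concatenate(([True], np.diff(times) > 0))
        times = times[keep]
    return SpikeTrain(times=times, duration=duration)


def _thin(parent: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    return parent[rng.random(parent.size) < c]


def generate_correlated_group(
    n: int, rate: float, c: float, duration: float, seed=None
) -> list[SpikeTrain]:
    """Generate ``n`` Poisson trains with pairwise zero-lag correlation ``c``.

    A single parent train of rate ``rate / c`` is generated, and each output
    train keeps every parent spike independently with probability ``c``.  Each
    output train is then Poisson with rate ``rate`` and every pair of outputs
    has binned-count correlation exactly ``c`` for any bin width.

    ``c = 0`` delegates to independent generation (the parent-rate
    construction diverges there); ``c = 1`` returns ``n`` copies of the
    parent.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("correlation c must lie in [0, 1]")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = as_seedseq(seed)
    if c == 0.0:
        children = ss.spawn(n)
        return [
            generate_homogeneous_poisson(rate, duration, child)
            for child in children
        ]
    rng = np.random.default_rng(ss)
    parent = generate_homogeneous_poisson(rate / c, duration, rng).times
    trains = []
    for _ in range(n):
        times = parent if c == 1.0 else _thin(parent, c, rng)
        trains.append(SpikeTrain(times=times, duration=duration))
    return trains


def measure_pairwise_correlation(
    trains: Sequence[SpikeTrain],
    bin_width: float = 10.0,
    max_pairs: int | None = None,
    seed=None,
) -> tuple[float, float]:
    """Mean pairwise Pearson correlation of binned spike counts.

    Returns ``(mean_correlation, standard_error)`` where the standard error
    is computed across pairs (pairs sharing a train are not independent, so
    this is a mildly optimistic error bar; it is used only as a sanity
    yardstick for the generator).

    Parameters
    ----------
    trains : sequence of SpikeTrain
        At least two trains with a common duration.
    bin_width : float
        Count bin width in ms; the thinning construction gives zero-lag
        correlations so the estimate is bin-width independent.
    max_pairs : int, optional
        If given, estimate from a random subsample of pairs.
    """
    if len(trains) < 2:
        raise ValueError("need at least two trains")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    duration = trains[0].duration
    if any(t.duration != duration for t in trains):
        raise ValueError("all trains must share the same duration")
    counts = np.stack([t.binned_counts(bin_width) for t in trains]).astype(np.float32)
    counts -= counts.mean(axis=1, keepdims=True)
    norms = np.sqrt((counts**2).sum(axis=1))
    norms[norms == 0] = np.inf
    m = len(trains)
    iu, ju = np.triu_indices(m, k=1)
    if max_pairs is not None and iu.size > max_pairs:
        sel = np.random.default_rng(seed).choice(iu.size, size=max_pairs, replace=False)
        iu, ju = iu[sel], ju[sel]
    # pairwise correlations without forming the full m x m matrix when subsampled
    if max_pairs is None:
        gram = counts @ counts.T
        corr = gram[iu, ju] / (norms[iu] * norms[ju])
    else:
        corr = np.einsum("ij,ij->i", counts[iu], counts[ju]) / (norms[iu] * norms[ju])
    corr = np.clip(np.asarray(corr, dtype=np.float64), -1.0, 1.0)
    se = float(corr.std(ddof=1) / np.sqrt(corr.size)) if corr.size > 1 else 0.0
    return float(corr.mean()), se


@dataclass
class InputEnsemble:
    """The full set of presynaptic inputs converging on the model neuron.

    ``N_ex`` excitatory and ``N_in`` inhibitory Poisson trains; an optional
    subgroup of the excitatory trains is pairwise correlated at zero lag with
    coefficient ``correlation`` (flagged by ``correlated_mask``).
    """

    excitatory_trains: list[SpikeTrain]
    inhibitory_trains: list[SpikeTrain]
    correlated_mask: np.ndarray
    rate_ex: float
    rate_in: float
    correlation: float
    seed: int | None = None
    duration: float = field(init=False)

    def __post_init__(self):
        self.correlated_mask = np.asarray(self.correlated_mask, dtype=bool)
        if self.correlated_mask.size != len(self.excitatory_trains):
            raise ValueError("correlated_mask length must equal the number of excitatory trains")
        self.duration = self.excitatory_trains[0].duration

    @property
    def n_ex(self) -> int:
        return len(self.excitatory_trains)

    @property
    def n_in(self) -> int:
        return len(self.inhibitory_trains)

    @classmethod
    def generate(
        cls,
        duration: float,
        n_ex: int = 1000,
        n_in: int = 250,
        rate_ex: float = 10.0,
        rate_in: float = 10.0,
        correlation: float = 0.0,
        frac_correlated: float = 0.5,
        seed=None,
    ) -> "InputEnsemble":
        """Generate a complete input ensemble from one master seed.

        The master seed is split into independent child streams (one per
        train) so the ensemble is reproducible and individual trains are
        statistically independent (apart from the designed correlation).
        """
        ss = as_seedseq(seed)
        n_corr = int(round(frac_correlated * n_ex)) if correlation > 0 else 0
        ss_corr, ss_unc, ss_in = ss.spawn(3)
        mask = np.zeros(n_ex, dtype=bool)
        mask[:n_corr] = True
        ex: list[SpikeTrain] = []
        if n_corr:
            ex.extend(generate_correlated_group(n_corr, rate_ex, correlation, duration, ss_corr))
        ex.extend(
            generate_homogeneous_poisson(rate_ex, duration, child)
            for child in ss_unc.spawn(n_ex - n_corr)
        )
        inh = [
            generate_homogeneous_poisson(rate_in, duration, child)
            for child in ss_in.spawn(n_in)
        ]
        return cls(
            excitatory_trains=ex,
            inhibitory_trains=inh,
            correlated_mask=mask,
            rate_ex=rate_ex,
            rate_in=rate_in,
            correlation=correlation,
            seed=seed if isinstance(seed, int) else None,
        )

    # -- serialization -----------------------------------------------------

    def to_csv(self, path) -> None:
        """Write all trains as (train_id, time_ms) rows plus a JSON sidecar.

        Excitatory trains get ids ``ex<i>``, inhibitory ``in<i>``.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("train_id,time_ms\n")
            for i, tr in enumerate(self.excitatory_trains):
                for t in tr.times:
                    fh.write(f"ex{i},{t:.6f}\n")
            for i, tr in enumerate(self.inhibitory_trains):
                for t in tr.times:
                    fh.write(f"in{i},{t:.6f}\n")
        meta = {
            "n_ex": self.n_ex,
            "n_in": self.n_in,
            "rate_ex_hz": self.rate_ex,
            "rate_in_hz": self.rate_in,
            "correlation": self.correlation,
            "correlated_mask": self.correlated_mask.astype(int).tolist(),
            "duration_ms": self.duration,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_csv(cls, path) -> "InputEnsemble":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        ids: dict[str, list[float]] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                tid, t = line.rstrip("\n").split(",")
                ids.setdefault(tid, []).append(float(t))
        dur = meta["duration_ms"]

        def train(tid):
            return SpikeTrain(np.array(ids.get(tid, []), dtype=float), dur)

        return cls(
            excitatory_trains=[train(f"ex{i}") for i in range(meta["n_ex"])],
            inhibitory_trains=[train(f"in{i}") for i in range(meta["n_in"])],
            correlated_mask=np.array(meta["correlated_mask"], dtype=bool),
            rate_ex=meta["rate_ex_hz"],
            rate_in=meta["rate_in_hz"],
            correlation=meta["correlation"],
            seed=meta["seed"],
        )
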