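"""4-nt kmer current-level models.

Nanopore current levels are determined by the few bases residing in the
pore constriction; a kmer model tabulates, for every length-k sequence,
the distribution of the median-normalized level it produces. Observed
kmer levels are modeled as normal distributions with mean mu_k and
standard deviation sigma_k, giving the per-level probability density

    P(I) = 1 / (sigma sqrt(2 pi)) * exp(-(I - mu)^2 / (2 sigma^2)).

A global sigma — the average of the per-kmer standard deviations —
generally outperforms kmer-specific sigmas in hypothesis testing and is
the default policy; per-kmer and manually set sigma remain available.

k = 4 keeps the data requirement low enough that a full single-XNA model
(512 kmers per XNA pair) is measurable from one flow-cell run. Each base
in a sequence is covered by four 4-mers, labeled by the focal base's
offset within the kmer: +2 (NNNX), +1 (NNXN), 0 (NXNN), -1 (XNNN).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContextError",
    "CoverageError",
    "ModelFormatError",
    "KmerStats",
    "KmerModel",
    "decompose",
    "fit",
    "kde_bandwidth",
    "kde_mode",
    "level_log10_pdf",
    "read_model",
    "write_model",
]

_LOG10 = math.log(10.0)

ESTIMATORS = ("mean", "median", "kde", "kde-mean")


class ContextError(ValueError):
    """A position lacks the flanking context its kmer decomposition needs."""


class CoverageError(KeyError):
    """A required kmer is absent from the model."""


class ModelFormatError(ValueError):
    """A model file violates the format contract."""


@dataclass(frozen=True)
class KmerStats:
    """Level statistics for one kmer.

    ``mu`` is the model level mean (per the chosen estimator); the
    remaining fields are summary statistics of the observed levels.
    """

    kmer: str
    mu: float
    sigma: float
    n_obs: int
    min: float = math.nan
    max: float = math.nan
    median: float = math.nan
    iqr: float = math.nan

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.kmer}: sigma must be >= 0")
        if self.n_obs < 0:
            raise ValueError(f"{self.kmer}: n_obs must be >= 0")


@dataclass
class KmerModel:
    """A kmer -> level-statistics table with a sigma policy.

    sigma_policy:
      * ``"global"`` (default) — every kmer uses the average of the
        per-kmer standard deviations;
      * ``"per_kmer"`` — each kmer uses its own sigma_k;
      * ``"manual"`` — a user-supplied sigma applies to all kmers.
    """

    k: int = 4
    entries: dict[str, KmerStats] = field(default_factory=dict)
    sigma_policy: str = "global"
    manual_sigma: float | None = None
    extra_columns: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sigma_policy not in ("global", "per_kmer", "manual"):
            raise ValueError(f"unknown sigma policy {self.sigma_policy!r}")
        for kmer in self.entries:
            if len(kmer) != self.k and not self._is_variant_kmer(kmer):
                raise ModelFormatError(f"kmer {kmer!r} does not have length {self.k}")

    def _is_variant_kmer(self, kmer: str) -> bool:
        # variant tokens ("Sn") make some kmers longer than k characters;
        # lowercase tag letters mark them
        return sum(c.isupper() for c in kmer) == self.k

    @property
    def global_sigma(self) -> float:
        """Mean of the per-kmer sigmas: the shared model sigma."""
        if not self.entries:
            raise ModelFormatError("empty model has no global sigma")
        return float(np.mean([s.sigma for s in self.entries.values()]))

    def sigma_for(self, kmer: str) -> float:
        if self.sigma_policy == "manual":
            if self.manual_sigma is None or self.manual_sigma <= 0:
                raise ValueError("manual sigma policy requires manual_sigma > 0")
            return self.manual_sigma
        if self.sigma_policy == "per_kmer":
            return self.require(kmer).sigma
        return self.global_sigma

    def mu(self, kmer: str) -> float:
        return self.require(kmer).mu

    def require(self, kmer: str) -> KmerStats:
        try:
            return self.entries[kmer]
        except KeyError:
            raise CoverageError(f"kmer {kmer!r} not covered by the model") from None

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def decompose(seq: str, focal_pos: int, k: int = 4) -> list[tuple[int, str]]:
    """The k kmers covering ``focal_pos``, as (offset, kmer) pairs.

    The offset labels the focal base's position within the kmer relative
    to the kmer's center (index 1): for k=4 the order is +2 (NNNX),
    +1 (NNXN), 0 (NXNN), -1 (XNNN). Requires k-1 flanking bases on each
    side (a heptamer context for k=4).
    """
    seq = str(seq)
    if not 0 <= focal_pos < len(seq):
        raise ContextError(f"focal position {focal_pos} outside sequence")
    if focal_pos < k - 1 or focal_pos + k - 1 >= len(seq):
        raise ContextError(
            f"position {focal_pos} lacks {k - 1}-base flanking context in "
            f"{len(seq)}-base sequence"
        )
    out = []
    for start in range(focal_pos - k + 1, focal_pos + 1):
        focal_index = focal_pos - start
        out.append((focal_index - 1, seq[start : start + k]))
    return out


def kde_bandwidth(levels: Sequence[float]) -> float:
    """Silverman rule-of-thumb bandwidth: BW = 0.9 min(IQR/1.34, sigma) n^(-1/5).

    Constant data (IQR = sigma = 0) falls back to a small positive
    bandwidth (1e-3) with a warning.
    """
    x = np.asarray(levels, dtype=float)
    if x.size < 1:
        raise ValueError("bandwidth needs at least one observation")
    sigma = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    a = 0.9 * min((q75 - q25) / 1.34, sigma)
    bw = a * x.size ** (-1.0 / 5.0)
    if bw <= 0:
        warnings.warn("degenerate (constant) levels: falling back to bandwidth 1e-3")
        return 1e-3
    return float(bw)


def _kde_grid(x: np.ndarray, bw: float, n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * math.sqrt(2 * math.pi))
    return grid, dens


def kde_mode(levels: Sequence[float], bw: float | None = None, n_grid: int = 512) -> float:
    """Mode of the Gaussian KDE on a fixed grid spanning the data +/- 3 BW."""
    x = np.asarray(levels, dtype=float)
    if bw is None:
        bw = kde_bandwidth(x)
    grid, dens = _kde_grid(x, bw, n_grid)
    return float(grid[np.argmax(dens)])


def _kde_mean(levels: Sequence[float], bw: float | None = None, n_grid: int = 512) -> float:
    x = np.asarray(levels, dtype=float)
    if bw is None:
        bw = kde_bandwidth(x)
    grid, dens = _kde_grid(x, bw, n_grid)
    return float(np.sum(grid * dens) / np.sum(dens))


def fit(
    levels_by_kmer: Mapping[str, Sequence[float]],
    estimator: str = "mean",
    k: int = 4,
    sigma_policy: str = "global",
) -> KmerModel:
    """Fit a kmer model from observed levels.

    ``estimator`` selects how mu_k is summarized: sample ``mean``, sample
    ``median``, KDE mode (``kde``), or KDE grid mean (``kde-mean``; for a
    symmetric kernel this tracks the sample mean). sigma_k is always the
    sample standard deviation. Kmers with zero observations are omitted
    and reported via a warning.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"estimator must be one of {ESTIMATORS}")
    if not levels_by_kmer:
        raise ValueError("no kmers to fit")
    entries: dict[str, KmerStats] = {}
    empty: list[str] = []
    for kmer, levels in levels_by_kmer.items():
        x = np.asarray(levels, dtype=float)
        if x.size == 0:
            empty.append(kmer)
            continue
        if estimator == "mean":
            mu = float(np.mean(x))
        elif estimator == "median":
            mu = float(np.median(x))
        elif estimator == "kde":
            mu = kde_mode(x) if x.size > 1 else float(x[0])
        else:
            mu = _kde_mean(x) if x.size > 1 else float(x[0])
        q75, q25 = np.percentile(x, [75, 25])
        entries[kmer] = KmerStats(
            kmer=kmer,
            mu=mu,
            sigma=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            n_obs=int(x.size),
            min=float(x.min()),
            max=float(x.max()),
            median=float(np.median(x)),
            iqr=float(q75 - q25),
        )
    if not entries:
        raise ValueError("every kmer had zero observations")
    if empty:
        warnings.warn(f"{len(empty)} kmer(s) had no observations and were omitted: {empty[:5]}...")
    return KmerModel(k=k, entries=entries, sigma_policy=sigma_policy)


def level_log10_pdf(level, mu, sigma):
    """log10 of the normal density N(mu, sigma) evaluated at ``level``.

    Vectorized over any broadcastable combination of arguments.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    level = np.asarray(level, dtype=float)
    mu = np.asarray(mu, dtype=float)
    z = (level - mu) / sigma
    ln_pdf = -0.5 * z * z - np.log(sigma * math.sqrt(2 * math.pi))
    out = ln_pdf / _LOG10
    return float(out) if out.ndim == 0 else out


MODEL_COLUMNS = ("kmer", "mean", "median", "std", "min", "max", "iqr", "coverage")


def write_model(model: KmerModel, path: str | Path, header_comments: Iterable[str] = ()) -> None:
    """Write a model CSV (one row per kmer, deterministic kmer order)."""
    rows = []
    for kmer in sorted(model.entries):
        s = model.entries[kmer]
        rows.append(
            {
                "kmer": kmer,
                "mean": s.mu,
                "median": s.median,
                "std": s.sigma,
                "min": s.min,
                "max": s.max,
                "iqr": s.iqr,
                "coverage": s.n_obs,
            }
        )
    df = pd.DataFrame(rows, columns=list(MODEL_COLUMNS))
    if model.extra_columns is not None:
        df = df.merge(model.extra_columns, on="kmer", how="left")
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_model(path: str | Path, sigma_policy: str = "global") -> KmerModel:
    """Read a model CSV; unknown extra columns are preserved."""
    df = pd.read_csv(path, comment="#", dtype={"kmer": str})
    missing = [c for c in ("kmer", "mean", "std", "coverage") if c not in df.columns]
    if missing:
        raise ModelFormatError(f"{path}: missing required column(s) {missing}")
    if df["kmer"].duplicated().any():
        dup = df["kmer"][df["kmer"].duplicated()].iloc[0]
        raise ModelFormatError(f"{path}: duplicate kmer row {dup!r}")
    k_len = int(df["kmer"].map(lambda s: sum(c.isupper() for c in s)).mode().iloc[0])
    entries = {}
    for row in df.itertuples(index=False):
        entries[row.kmer] = KmerStats(
            kmer=row.kmer,
            mu=float(row.mean),
            sigma=float(row.std),
            n_obs=int(row.coverage),
            min=float(getattr(row, "min", math.nan)),
            max=float(getattr(row, "max", math.nan)),
            median=float(getattr(row, "median", math.nan)),
            iqr=float(getattr(row, "iqr", math.nan)),
        )
    extra = [c for c in df.columns if c not in MODEL_COLUMNS]
    extra_df = df[["kmer"] + extra] if extra else None
    return KmerModel(k=k_len, entries=entries, sigma_policy=sigma_policy, extra_columns=extra_df)
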