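"""The 16-feature battery computed on 2560-sample windows.

Three groups:

* statistical — Mean, SD (population denominator), kurtosis (raw fourth
  standardised moment, not excess) and skewness;
* entropy — sample (SE), fuzzy (FE), Shannon (SnE), Renyi (RE),
  permutation (PE), distribution (DE) and singular-value-decomposition
  (SVDE) entropies;
* frequency — band powers (delta/theta/alpha/beta) from a Welch
  periodogram plus spectral entropy (SpE).

Log bases follow the defining formulas: natural log for SE, FE, SnE, RE
and SpE; base 2 for PE, DE and SVDE.  Everything is overridable through
:class:`FeatureParams`, whose defaults are the common choices of the
driver-fatigue entropy literature (m=2, r=0.2*SD, order-3 ordinal
patterns, alpha=2, 64 histogram bins, 10-dimensional delay embedding).

SE and FE share one O(N^2) template-matching pass; a numba kernel is used
when available with a chunked numpy fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import welch

from eegfatigue.constants import BANDS, FEATURE_NAMES, SAMPLING_RATE
from eegfatigue.errors import AggregationError
from eegfatigue.segmentation import DEFAULT_SCHEDULE, Recording, iter_segments

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureParams",
    "compute_moments",
    "compute_regularity_entropies",
    "compute_symbolic_entropies",
    "compute_distribution_entropies",
    "compute_spectral",
    "compute_feature_vector",
    "aggregate_event_features",
    "extract_feature_table",
]


@dataclass(frozen=True)
class FeatureParams:
    """Hyperparameters of the feature battery."""

    m: int = 2                      # embedding dimension for SE / FE
    r: float = 0.2                  # tolerance as a fraction of the segment SD
    fuzzy_exponent: float = 2.0     # n in exp(-(d/r_tol)^n)
    pe_order: int = 3
    pe_delay: int = 1
    renyi_alpha: float = 2.0
    histogram_bins: int = 64
    svd_embed_dim: int = 10
    svd_delay: int = 1
    bands: tuple = BANDS
    spectral_range: tuple[float, float] = (0.4, 30.0)
    welch_nperseg: int = 256
    welch_overlap: float = 0.5
    sampling_rate: int = SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance fraction r must be > 0")
        if self.pe_order < 2 or self.pe_delay < 1:
            raise ValueError("pe_order must be >= 2 and pe_delay >= 1")
        if self.renyi_alpha <= 0 or self.renyi_alpha == 1.0:
            raise ValueError("renyi_alpha must be > 0 and != 1")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.svd_embed_dim < 2 or self.svd_delay < 1:
            raise ValueError("svd_embed_dim must be >= 2 and svd_delay >= 1")
        lows = [lo for _, lo, _ in self.bands]
        highs = [hi for _, _, hi in self.bands]
        if any(hi <= lo for lo, hi in zip(lows, highs)) or any(
            nxt < prev for prev, nxt in zip(highs, lows[1:])
        ):
            raise ValueError("band edges must be increasing and non-overlapping")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")

    def to_metadata(self) -> dict:
        meta = asdict(self)
        meta["log_bases"] = {
            "SE": "e", "FE": "e", "SnE": "e", "RE": "e", "SpE": "e",
            "PE": "2", "DE": "2", "SVDE": "2",
        }
        return meta

    def with_(self, **kwargs) -> "FeatureParams":
        return replace(self, **kwargs)


DEFAULT_PARAMS = FeatureParams()


# ---------------------------------------------------------------------------
# Statistical moments
# ---------------------------------------------------------------------------

def compute_moments(segment: np.ndarray) -> tuple[float, float, float, float]:
    """Population-denominator mean, SD, kurtosis and skewness.

    Zero-variance segments carry no shape information: kurtosis and
    skewness are set to the 0.0 sentinel (logged at debug level).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("moments need at least two samples")
    mean = float(np.mean(x))
    centred = x - mean
    var = float(np.mean(centred**2))
    sd = math.sqrt(var)
    if sd == 0.0:
        logger.debug("zero-variance segment: Kur/SK set to sentinel 0.0")
        return mean, 0.0, 0.0, 0.0
    kur = float(np.mean(centred**4)) / var**2
    sk = float(np.mean(centred**3)) / var**1.5
    return mean, sd, kur, sk


# ---------------------------------------------------------------------------
# Sample + fuzzy entropy (shared template-matching pass)
# ---------------------------------------------------------------------------

def _sampen_fuzzy_py(x: np.ndarray, m: int, r: float, n_exp: float):
    """Chunked numpy fallback for the pair scan: returns (B, A, phi_m, phi_m1).

    B/A count Chebyshev template matches at lengths m and m+1; phi_m and
    phi_m1 accumulate the fuzzy membership degrees exp(-(d/r)^n) over the
    same pairs.  Pairs are i < j over the first N-m templates (self-matches
    excluded).
    """
    n = len(x)
    nt = n - m
    emb = sliding_window_view(x, m + 1)[:nt]  # (nt, m+1)
    B = 0
    A = 0
    phi_m = 0.0
    phi_m1 = 0.0
    chunk = max(1, int(2e6) // max(nt, 1))
    for start in range(0, nt - 1, chunk):
        stop = min(start + chunk, nt - 1)
        block = emb[start:stop]  # (b, m+1)
        # distances to all following templates
        diff = np.abs(block[:, None, :] - emb[None, :, :])  # (b, nt, m+1)
        d_m = diff[:, :, :m].max(axis=2)
        d_m1 = np.maximum(d_m, diff[:, :, m])
        # keep only j > i
        idx_i = np.arange(start, stop)[:, None]
        idx_j = np.arange(nt)[None, :]
        mask = idx_j > idx_i
        d_m = d_m[mask]
        d_m1 = d_m1[mask]
        B += int(np.count_nonzero(d_m <= r))
        A += int(np.count_nonzero(d_m1 <= r))
        phi_m += float(np.sum(np.exp(-((d_m / r) ** n_exp))))
        phi_m1 += float(np.sum(np.exp(-((d_m1 / r) ** n_exp))))
    return B, A, phi_m, phi_m1


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _sampen_fuzzy_nb(x, m, r, n_exp):  # pragma: no cover - jitted
        n = x.shape[0]
        nt = n - m
        B = 0
        A = 0
        phi_m = 0.0
        phi_m1 = 0.0
        inv_r = 1.0 / r
        squared = n_exp == 2.0
        # memberships below exp(-38) ~ 3e-17 vanish in the double-precision
        # pair sums, so pairs beyond the cutoff distance contribute nothing
        cut = r * math.exp(math.log(38.0) / n_exp)
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    t = abs(x[i + k] - x[j + k])
                    if t > d:
                        d = t
                t = abs(x[i + m] - x[j + m])
                d1 = d if d > t else t
                if d > cut:
                    continue
                if d <= r:
                    B += 1
                    if d1 <= r:
                        A += 1
                u = d * inv_r
                if squared:
                    phi_m += math.exp(-(u * u))
                    if d1 <= cut:
                        u1 = d1 * inv_r
                        phi_m1 += math.exp(-(u1 * u1))
                else:
                    phi_m += math.exp(-(u**n_exp))
                    if d1 <= cut:
                        u1 = d1 * inv_r
                        phi_m1 += math.exp(-(u1**n_exp))
        return B, A, phi_m, phi_m1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _sampen_fuzzy_core(x: np.ndarray, m: int, r: float, n_exp: float):
    if _HAVE_NUMBA:
        return _sampen_fuzzy_nb(x, m, r, n_exp)
    return _sampen_fuzzy_py(x, m, r, n_exp)


def sample_entropy_cap(n: int, m: int) -> float:
    """Finite-sample cap used when no length-(m+1) matches exist."""
    return -math.log(2.0 / ((n - m - 1) * (n - m)))


def compute_regularity_entropies(
    segment: np.ndarray, params: FeatureParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """Sample entropy and fuzzy entropy of one segment.

    The tolerance is ``params.r`` times the segment's population SD.  SE is
    the negative natural log of the ratio of length-(m+1) to length-m
    Chebyshev template matches (self-matches excluded); undefined ratios
    (zero matches) are capped at the maximum observable value
    ``-log(2/((N-m-1)(N-m)))``.  FE replaces the hard match with the
    membership degree ``exp(-(d/r_tol)^n)`` averaged over the same pairs.
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    m = params.m
    if n <= m + 1:
        raise ValueError(f"segment too short for m={m}: N={n}")
    sd = float(np.std(x))
    if sd == 0.0:
        # constant segment: every template matches exactly, all memberships 1
        return 0.0, 0.0
    r_tol = params.r * sd
    B, A, phi_m, phi_m1 = _sampen_fuzzy_core(x, m, r_tol, params.fuzzy_exponent)
    if A > 0 and B > 0:
        se = -math.log(A / B)
    else:
        se = sample_entropy_cap(n, m)
        logger.debug("sample entropy undefined (A=%d, B=%d): capped at %.4f", A, B, se)
    fe = -math.log(phi_m1 / phi_m)
    return se, fe


# ---------------------------------------------------------------------------
# Permutation + SVD entropy
# ---------------------------------------------------------------------------

def _delay_embedding(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n_vectors = len(x) - (dim - 1) * delay
    if n_vectors < 1:
        raise ValueError(f"segment too short for embedding dim={dim}, delay={delay}")
    idx = np.arange(n_vectors)[:, None] + np.arange(dim)[None, :] * delay
    return x[idx]


def _shannon(p: np.ndarray, base: float) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / math.log(base))


def compute_symbolic_entropies(
    segment: np.ndarray, params: FeatureParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """Permutation entropy (bits) and SVD entropy (bits).

    PE is the base-2 Shannon entropy of the ordinal-pattern distribution
    (order ``pe_order``, delay ``pe_delay``); tied samples are resolved by
    stable index order.  SVDE is the base-2 Shannon entropy of the squared
    singular values of the delay-embedding trajectory matrix, normalised
    to sum to one.
    """
    x = np.asarray(segment, dtype=float)

    emb = _delay_embedding(x, params.pe_order, params.pe_delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    weights = math.factorial(params.pe_order) ** np.arange(params.pe_order)
    codes = patterns @ weights
    _, counts = np.unique(codes, return_counts=True)
    pe = _shannon(counts / counts.sum(), base=2.0)

    traj = _delay_embedding(x, params.svd_embed_dim, params.svd_delay)
    sv = np.linalg.svd(traj, compute_uv=False)
    energy = sv**2
    total = energy.sum()
    if total == 0.0:
        svde = 0.0
    else:
        svde = _shannon(energy / total, base=2.0)
    return pe, svde


# ---------------------------------------------------------------------------
# Amplitude-distribution entropies
# ---------------------------------------------------------------------------

def compute_distribution_entropies(
    segment: np.ndarray, params: FeatureParams = DEFAULT_PARAMS
) -> tuple[float, float, float]:
    """Shannon (nats), Renyi (nats, order alpha) and distribution (bits)
    entropy of the equal-width amplitude histogram over [min, max].

    Empty bins are excluded from every sum; a zero-range (constant)
    segment occupies a single bin, so all three entropies are 0.
    """
    x = np.asarray(segment, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0, 0.0, 0.0
    counts, _ = np.histogram(x, bins=params.histogram_bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    sne = float(-np.sum(p * np.log(p)))
    alpha = params.renyi_alpha
    re = float(math.log(np.sum(p**alpha)) / (1.0 - alpha))
    de = float(-np.sum(p * np.log2(p)))
    return sne, re, de


# ---------------------------------------------------------------------------
# Spectral features
# ---------------------------------------------------------------------------

def _welch_psd(x: np.ndarray, params: FeatureParams):
    nperseg = min(params.welch_nperseg, len(x))
    noverlap = int(nperseg * params.welch_overlap)
    return welch(
        x,
        fs=params.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
    )


def compute_spectral(
    segment: np.ndarray, params: FeatureParams = DEFAULT_PARAMS
) -> tuple[float, float, float, float, float]:
    """Band powers (delta, theta, alpha, beta) and spectral entropy.

    The PSD is a Welch-averaged periodogram (256-sample Hann windows, 50%
    overlap, per-window mean removal -> 1 Hz resolution).  Band power is
    the rectangle-rule integral of the PSD over the half-open band
    [f_low, f_high).  SpE is the natural-log Shannon entropy of the PSD
    normalised to a probability distribution over the analysis range.
    """
    x = np.asarray(segment, dtype=float)
    freqs, psd = _welch_psd(x, params)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0

    powers = []
    for _, lo, hi in params.bands:
        mask = (freqs >= lo) & (freqs < hi)
        powers.append(float(np.sum(psd[mask]) * df))

    lo, hi = params.spectral_range
    mask = (freqs >= lo) & (freqs < hi)
    band_psd = psd[mask]
    total = band_psd.sum()
    if total <= 0.0:
        spe = 0.0
    else:
        spe = _shannon(band_psd / total, base=math.e)
    return (*powers, spe)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def compute_feature_vector(
    segment: np.ndarray, params: FeatureParams = DEFAULT_PARAMS
) -> np.ndarray:
    """All 16 features in the fixed :data:`FEATURE_NAMES` order."""
    mean, sd, kur, sk = compute_moments(segment)
    se, fe = compute_regularity_entropies(segment, params)
    sne, re, de = compute_distribution_entropies(segment, params)
    pe, svde = compute_symbolic_entropies(segment, params)
    delta, theta, alpha, beta, spe = compute_spectral(segment, params)
    vec = np.array(
        [mean, sd, kur, sk, se, fe, sne, re, pe, de, svde, delta, theta, alpha, beta, spe]
    )
    assert vec.shape == (len(FEATURE_NAMES),)
    return vec


def aggregate_event_features(vectors) -> np.ndarray:
    """Element-wise arithmetic mean: one representative vector per event."""
    vectors = list(vectors)
    if not vectors:
        raise AggregationError("cannot aggregate an empty list of feature vectors")
    stacked = np.vstack(vectors)
    return stacked.mean(axis=0)


def extract_feature_table(
    recordings,
    params: FeatureParams = DEFAULT_PARAMS,
    schedule=DEFAULT_SCHEDULE,
    average: str = "features",
    preprocess=None,
    events=None,
):
    """Per-(subject, session, channel, event) representative feature vectors.

    ``recordings`` is an iterable of :class:`Recording` or of
    ``(Recording, EventSchedule)`` pairs (per-recording schedules).

    ``average`` selects where the within-event averaging happens:
    ``"features"`` (default) averages the per-window feature vectors;
    ``"signal"`` averages the raw windows sample-wise first and computes
    features on the mean window.

    ``events`` optionally restricts extraction to a subset of events
    (e.g. only the task events the modelling table consumes).
    """
    import pandas as pd

    if average not in ("features", "signal"):
        raise ValueError(f"average must be 'features' or 'signal', got {average!r}")
    keep = set(events) if events is not None else None

    rows = []
    for item in recordings:
        rec, sched = item if isinstance(item, tuple) else (item, schedule)
        buckets: dict[tuple[str, str], list[np.ndarray]] = {}
        for seg in iter_segments(rec, sched, preprocess=preprocess):
            if keep is not None and seg.event not in keep:
                continue
            buckets.setdefault((seg.channel, seg.event), []).append(seg.samples)
        for (channel, event), windows in buckets.items():
            if average == "features":
                rep = aggregate_event_features(
                    [compute_feature_vector(w, params) for w in windows]
                )
            else:
                rep = compute_feature_vector(np.vstack(windows).mean(axis=0), params)
            row = {
                "subject": rec.subject_id,
                "session": rec.session_index,
                "channel": channel,
                "event": event,
            }
            row.update(dict(zip(FEATURE_NAMES, rep)))
            rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["subject", "session", "channel", "event"]).reset_index(
            drop=True
        )
    return frame
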