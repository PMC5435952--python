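"""Fuzzy entropy (FuzzyEn) of a scalar time series.

FuzzyEn measures the irregularity of a signal as the negative log-ratio of
average fuzzy similarity between phase-space vectors at embedding dimensions
``m`` and ``m + 1``::

    FuzzyEn(m, n, r, N) = ln phi_m(n, r) - ln phi_{m+1}(n, r)

where ``phi_d`` averages, over all ordered pairs of distinct embedded
windows, an exponential membership of their Chebyshev distance.  Each
window is centred by its own local mean before distances are taken, which
makes the measure insensitive to slow baseline drift.  Compared with sample
entropy the hard tolerance threshold is replaced by a smooth exponential
similarity, so the statistic varies continuously with the data.

Two similarity kernels are provided:

``as_printed``
    ``exp(-d**n / r)`` — the default form used throughout this package.
``normalized``
    ``exp(-(d/r)**n)`` — the form common in the wider FuzzyEn literature;
    it renders the statistic invariant to amplitude rescaling because the
    tolerance ``r = r_factor * SD`` scales with the data.

The module exposes a vectorised fast path (:func:`fuzzy_entropy`) and a
deliberately naive loop-by-loop reference (:func:`fuzzy_entropy_oracle`)
that exists so the fast path can be checked against an independent
transcription of the definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "FuzzyEnParams",
    "embed_windows",
    "chebyshev_distance",
    "similarity",
    "phi",
    "fuzzy_entropy",
    "fuzzy_entropy_oracle",
]

_SIMILARITY_FORMS = ("as_printed", "normalized")


@dataclass(frozen=True)
class FuzzyEnParams:
    """Parameters of the fuzzy-entropy statistic.

    Attributes
    ----------
    m : int
        Embedding dimension (window length of the phase-space vectors).
    n : float
        Gradient of the exponential membership function; larger ``n``
        steepens the decay of similarity with distance.
    r_factor : float
        Similarity tolerance as a fraction of the series' population
        standard deviation; the effective width ``r = r_factor * SD(x)``
        is recomputed for every input series.
    similarity_form : str
        ``"as_printed"`` (``exp(-d**n / r)``, default) or ``"normalized"``
        (``exp(-(d/r)**n)``).
    """

    m: int = 2
    n: float = 4.0
    r_factor: float = 0.2
    similarity_form: str = "as_printed"

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ValueError(f"embedding dimension m must be a positive integer, got {self.m!r}")
        if not self.n > 0:
            raise ValueError(f"gradient n must be positive, got {self.n!r}")
        if not self.r_factor > 0:
            raise ValueError(f"r_factor must be positive, got {self.r_factor!r}")
        if self.similarity_form not in _SIMILARITY_FORMS:
            raise ValueError(
                f"similarity_form must be one of {_SIMILARITY_FORMS}, got {self.similarity_form!r}"
            )


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite samples (NaN or Inf)")
    return x


def embed_windows(x, m: int, n_vectors: int | None = None) -> np.ndarray:
    """Embed ``x`` into locally-centred sliding windows of length ``m``.

    Window ``i`` (0-based) is ``(x[i], ..., x[i+m-1])`` minus the mean of
    those same ``m`` samples, so each row sums to zero.  By default the
    first ``N - m`` windows are returned; ``n_vectors`` overrides the count
    so that the dimension-``m`` and dimension-``m+1`` embeddings used by
    :func:`fuzzy_entropy` contain the same number of vectors.

    Parameters
    ----------
    x : array_like
        Input series of length ``N >= m + 2``.
    m : int
        Window length, ``m >= 1``.
    n_vectors : int, optional
        Number of leading windows to expose (at most ``N - m + 1``).

    Returns
    -------
    numpy.ndarray of shape ``(n_vectors, m)``
    """
    x = _as_series(x)
    N = x.size
    if m < 1:
        raise ValueError(f"embedding dimension m must be >= 1, got {m}")
    if N < m + 2:
        raise ValueError(
            f"series too short for embedding: N={N} but need N >= m + 2 = {m + 2}"
        )
    if n_vectors is None:
        n_vectors = N - m
    if not 1 <= n_vectors <= N - m + 1:
        raise ValueError(f"n_vectors={n_vectors} outside valid range [1, {N - m + 1}]")
    # stride trick view, then centre each window by its own mean
    idx = np.arange(n_vectors)[:, None] + np.arange(m)[None, :]
    windows = x[idx]
    return windows - windows.mean(axis=1, keepdims=True)


def chebyshev_distance(v1, v2) -> float:
    """Maximum absolute component-wise difference between two vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    return float(np.max(np.abs(v1 - v2)))


def similarity(d, n: float, r: float, form: str = "as_printed"):
    """Fuzzy membership of a Chebyshev distance ``d`` given tolerance ``r``.

    ``as_printed`` evaluates ``exp(-d**n / r)``; ``normalized`` evaluates
    ``exp(-(d/r)**n)``.  Both map ``d = 0`` to 1 and decrease strictly
    with ``d``.
    """
    if r <= 0:
        raise ValueError(f"similarity tolerance r must be positive, got {r!r}")
    if form not in _SIMILARITY_FORMS:
        raise ValueError(f"unknown similarity form {form!r}")
    d = np.asarray(d, dtype=float)
    # integral gradients take numpy's fast power path
    if float(n).is_integer():
        n = int(n)
    if form == "as_printed":
        out = np.exp(-(d**n) / r)
    else:
        out = np.exp(-((d / r) ** n))
    return float(out) if out.ndim == 0 else out


def phi(x, dim: int, params: FuzzyEnParams, r: float | None = None,
        n_vectors: int | None = None) -> float:
    """Average fuzzy similarity ``phi_dim(n, r)`` of the embedded series.

    For each of the embedded vectors, the similarities to every *other*
    vector are averaged; ``phi`` is the mean of those per-vector averages.
    ``r`` defaults to ``params.r_factor * SD(x)`` (population SD); it can
    be passed explicitly so that both dimensions of the entropy share the
    tolerance computed once on the raw series.
    """
    x = _as_series(x)
    if r is None:
        r = params.r_factor * float(np.std(x))
    vecs = embed_windows(x, dim, n_vectors=n_vectors)
    M = vecs.shape[0]
    if M < 2:
        raise ValueError(f"need at least 2 embedded vectors, got {M}")
    # condensed pairwise distances: S is symmetric and S_ii = 1 exactly,
    # so phi = mean_i mean_{j != i} S_ij = 2 * sum_{i<j} S_ij / (M (M - 1))
    d = pdist(vecs, metric="chebyshev")
    S = similarity(d, params.n, r, params.similarity_form)
    return float(2.0 * S.sum() / (M * (M - 1)))


def fuzzy_entropy(x, params: FuzzyEnParams = FuzzyEnParams()) -> float:
    """Fuzzy entropy ``ln phi_m - ln phi_{m+1}`` of a series.

    The tolerance ``r = r_factor * SD(x)`` is computed once on the input
    series with the population standard deviation.  Both dimensions use
    the same ``N - m`` embedded vectors so their averages are comparable.
    A constant series (``SD = 0``) carries no complexity: the function
    warns and returns 0 rather than dividing by a zero tolerance.

    Returns
    -------
    float
        Non-negative for typical signals; exactly 0 for constant and
        affine-ramp inputs, whose centred windows are all identical.
    """
    x = _as_series(x)
    m = params.m
    if x.size < m + 2:
        raise ValueError(
            f"series too short: N={x.size} but fuzzy entropy needs N >= m + 2 = {m + 2}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("constant series has zero SD; fuzzy entropy defined as 0", stacklevel=2)
        return 0.0
    r = params.r_factor * sd
    count = x.size - m
    phi_m = phi(x, m, params, r=r, n_vectors=count)
    phi_m1 = phi(x, m + 1, params, r=r, n_vectors=count)
    return float(np.log(phi_m) - np.log(phi_m1))


def fuzzy_entropy_oracle(x, params: FuzzyEnParams = FuzzyEnParams()) -> float:
    """Literal, loop-by-loop transcription of the fuzzy-entropy definition.

    Intentionally unoptimised (pure-Python triple loops); used in the test
    suite as an independent cross-check of :func:`fuzzy_entropy`.  Suitable
    only for short series (roughly ``N <= 500``).
    """
    x = _as_series(x)
    m = params.m
    N = x.size
    if N < m + 2:
        raise ValueError(
            f"series too short: N={N} but fuzzy entropy needs N >= m + 2 = {m + 2}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("constant series has zero SD; fuzzy entropy defined as 0", stacklevel=2)
        return 0.0
    r = params.r_factor * sd

    def _phi(dim: int) -> float:
        count = N - m  # same number of vectors at both dimensions
        vectors = []
        for i in range(count):
            window = [x[i + k] for k in range(dim)]
            mean_i = sum(window) / dim
            vectors.append([v - mean_i for v in window])
        outer = 0.0
        for i in range(count):
            inner = 0.0
            for j in range(count):
                if j == i:
                    continue
                d = max(abs(vectors[i][k] - vectors[j][k]) for k in range(dim))
                if params.similarity_form == "as_printed":
                    inner += np.exp(-(d**params.n) / r)
                else:
                    inner += np.exp(-((d / r) ** params.n))
            outer += inner / (count - 1)
        return outer / count

    return float(np.log(_phi(m)) - np.log(_phi(m + 1)))
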