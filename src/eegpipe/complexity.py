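"""Window-level complexity features: approximate entropy and Higuchi fractal dimension.

Approximate entropy (ApEn) quantifies the regularity of a short time series:
it is the negative log conditional probability that runs of ``m`` samples that
are close (Chebyshev distance within a tolerance ``r``) remain close when
extended to ``m + 1`` samples.  Larger values mean a less predictable signal.
With the tolerance tied to the window's standard deviation the statistic is
exactly scale- and translation-invariant, which is what makes it usable on
EEG of arbitrary amplitude calibration.

Higuchi's method estimates a curve's fractal dimension ``D`` from the scaling
of the average curve length ``L(k)`` computed at sample delays ``k = 1..k_max``:
``L(k) ~ k^-D``, so ``D`` is the least-squares slope of ``ln L(k)`` against
``ln(1/k)``.  A smooth line gives ``D = 1``; white noise approaches ``D = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, NoMatchError, ValidationError

__all__ = [
    "ApEnParams",
    "ApEnComputation",
    "apen",
    "HiguchiParams",
    "HiguchiResult",
    "higuchi_fd",
]

#: Minimum window length for a meaningful ApEn estimate.
APEN_MIN_SAMPLES = 50


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of the approximate-entropy statistic.

    Parameters
    ----------
    m
        Embedding run length (template length). ``m = 2`` is the standard
        choice for short physiological records.
    r_coefficient
        Tolerance as a multiple of the window's standard deviation;
        ``0.1`` is the conventional value for EEG.
    self_match
        ``"include"`` (default) counts the ``j = i`` pair, as in the
        classical definition, which guarantees every match frequency is
        positive; ``"exclude"`` skips it, and then raises
        :class:`NoMatchError` whenever a template has no other neighbour
        within ``r`` (the per-template log is undefined).  At these window
        lengths and tolerances the exclude convention is undefined for most
        realistic signals, which is why include is the default; the two
        differ by O(1/N) whenever both are defined.
    """

    m: int = 2
    r_coefficient: float = 0.1
    self_match: str = "include"

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError(f"embedding length m must be >= 1, got {self.m}")
        if not self.r_coefficient > 0:
            raise ValidationError(
                f"r_coefficient must be > 0, got {self.r_coefficient}"
            )
        if self.self_match not in ("exclude", "include"):
            raise ValidationError(
                f"self_match must be 'exclude' or 'include', got {self.self_match!r}"
            )


@dataclass(frozen=True)
class ApEnComputation:
    """Full trace of one ApEn evaluation.

    Attributes
    ----------
    n_samples
        Window length N.
    r
        Absolute tolerance actually used.
    counts_m, counts_m1
        Per-template match counts at dimensions ``m`` and ``m + 1``.
    c_m, c_m1
        Match frequencies (counts divided by the number of templates at the
        respective dimension).
    phi_m, phi_m1
        Mean natural log of the match frequencies at ``m`` and ``m + 1``.
    value
        ``phi_m - phi_m1``, the approximate entropy.
    """

    n_samples: int
    r: float
    counts_m: np.ndarray = field(repr=False)
    counts_m1: np.ndarray = field(repr=False)
    c_m: np.ndarray = field(repr=False)
    c_m1: np.ndarray = field(repr=False)
    phi_m: float = 0.0
    phi_m1: float = 0.0
    value: float = 0.0


def _chebyshev_template_distances(x: np.ndarray, m: int) -> np.ndarray:
    """Pairwise Chebyshev distances between all m-length templates of ``x``.

    Built incrementally from the scalar absolute-difference matrix:
    ``d_m(i, j) = max_{k<m} |x[i+k] - x[j+k]|`` is a running maximum over
    diagonals, so dimension m+1 reuses dimension m's work.
    """
    n_templates = len(x) - m + 1
    diff = np.abs(x[:, None] - x[None, :])
    d = diff[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(d, diff[k : k + n_templates, k : k + n_templates], out=d)
    return d


def _phi(x: np.ndarray, q: int, r: float, exclude_self: bool):
    """Mean log match frequency at embedding dimension ``q``.

    The denominator of each frequency is the template count ``N - q + 1``
    regardless of the self-match convention; excluding the self match only
    removes it from the numerator.
    """
    n_templates = len(x) - q + 1
    d = _chebyshev_template_distances(x, q)
    match = d <= r
    counts = match.sum(axis=1)
    if exclude_self:
        counts = counts - 1  # the diagonal always matches (d = 0 <= r)
        if np.any(counts == 0):
            idx = int(np.argmax(counts == 0))
            raise NoMatchError(template_index=idx, dimension=q)
    c = counts / n_templates
    phi = float(np.mean(np.log(c)))
    return counts, c, phi


def apen(
    samples,
    params: ApEnParams = ApEnParams(),
    r_absolute: float | None = None,
) -> ApEnComputation:
    """Approximate entropy of a single window.

    Parameters
    ----------
    samples
        1-D sequence of at least ``APEN_MIN_SAMPLES`` finite values.
    params
        Embedding length, tolerance coefficient and self-match convention.
    r_absolute
        If given, used directly as the tolerance instead of
        ``r_coefficient * SD(samples)`` (population SD, ddof=0).  Required
        for constant windows, whose SD is zero.

    Returns
    -------
    ApEnComputation
        The value together with the per-template counts and frequencies of
        both embedding passes.

    Raises
    ------
    ValidationError
        Fewer than 50 samples, non-finite samples, or N too small for the
        chosen ``m``.
    DegenerateInputError
        Zero-variance window without an explicit ``r_absolute``.
    NoMatchError
        Some template has no neighbour within ``r`` under the exclude
        convention (log of zero frequency is undefined).
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if n < APEN_MIN_SAMPLES:
        raise ValidationError(
            f"ApEn needs at least {APEN_MIN_SAMPLES} samples, got {n}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")
    if n - params.m < 2:
        raise ValidationError(f"window of {n} samples too short for m={params.m}")

    if r_absolute is not None:
        if not r_absolute > 0:
            raise ValidationError(f"r_absolute must be > 0, got {r_absolute}")
        r = float(r_absolute)
    else:
        sd = float(np.std(x))  # population SD: divide by N
        if sd == 0.0:
            raise DegenerateInputError(
                "constant window has zero SD; pass r_absolute to analyse it"
            )
        r = params.r_coefficient * sd

    exclude = params.self_match == "exclude"
    counts_m, c_m, phi_m = _phi(x, params.m, r, exclude)
    counts_m1, c_m1, phi_m1 = _phi(x, params.m + 1, r, exclude)
    return ApEnComputation(
        n_samples=n,
        r=r,
        counts_m=counts_m,
        counts_m1=counts_m1,
        c_m=c_m,
        c_m1=c_m1,
        phi_m=phi_m,
        phi_m1=phi_m1,
        value=phi_m - phi_m1,
    )


@dataclass(frozen=True)
class HiguchiParams:
    """Maximum delay for the Higuchi length curve. Needs ``k_max >= 2`` for a slope."""

    k_max: int = 8

    def __post_init__(self):
        if self.k_max < 2:
            raise ValidationError(
                f"k_max must be >= 2 (the slope needs >= 2 points), got {self.k_max}"
            )


@dataclass(frozen=True)
class HiguchiResult:
    """Average curve lengths L(k) for k = 1..k_max and the fitted dimension D."""

    lengths: np.ndarray = field(repr=False)
    dimension: float = 0.0


def higuchi_fd(samples, params: HiguchiParams = HiguchiParams()) -> HiguchiResult:
    """Higuchi fractal dimension of a single window.

    For each delay ``k`` and offset ``m = 1..k`` the decimated series
    ``x(m), x(m+k), x(m+2k), ...`` has curve length

    ``L_m(k) = [ sum |x(m+ik) - x(m+(i-1)k)| ] * (N-1) / (floor((N-m)/k) * k) / k``

    and ``L(k)`` is the average of ``L_m(k)`` over the ``k`` offsets.  ``D``
    is the slope of the least-squares line of ``ln L(k)`` on ``ln(1/k)``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples must be finite")
    if n <= 2 * params.k_max:
        raise ValidationError(
            f"need N > 2*k_max samples; got N={n} with k_max={params.k_max}"
        )
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("constant input has no curve length")

    lengths = np.empty(params.k_max)
    for k in range(1, params.k_max + 1):
        lm = np.empty(k)
        for m in range(1, k + 1):
            n_steps = (n - m) // k
            idx = m - 1 + k * np.arange(n_steps + 1)
            total = np.abs(np.diff(x[idx])).sum()
            lm[m - 1] = total * (n - 1) / (n_steps * k) / k
        lengths[k - 1] = lm.mean()

    k_arr = np.arange(1, params.k_max + 1, dtype=float)
    slope = np.polyfit(np.log(1.0 / k_arr), np.log(lengths), 1)[0]
    if not np.isfinite(slope):
        raise DegenerateInputError("fractal dimension fit did not converge")
    return HiguchiResult(lengths=lengths, dimension=float(slope))
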