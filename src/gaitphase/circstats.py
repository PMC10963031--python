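"""Circular statistics: mean resultant vector, angular deviation, and a
two-sample angular permutation test.

The mean vector of a set of angles (optionally weighted) summarises a
circular distribution by its resultant length R in [0, 1] and angle.
R = 1 means all mass at one angle, R = 0 a balanced distribution. The
angular deviation s = sqrt(2(1 - R)) is the circular analogue of the
standard deviation (Zar's angular deviation).

The two-sample test compares the unit-weight mean vectors of two groups
of angles by the Euclidean distance between the resultant vectors in the
plane, against a label-shuffling null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeanVector",
    "mean_vector",
    "angular_deviation",
    "angular_permutation_test",
    "bonferroni",
]


@dataclass(frozen=True)
class MeanVector:
    """Resultant vector of a circular distribution."""

    length: float
    angle_deg: float

    @property
    def defined(self) -> bool:
        """Angle is undefined for a vanishing resultant."""
        return self.length > 1e-12


def mean_vector(angles_deg, weights=None) -> MeanVector:
    """Weighted circular mean vector.

    R e^{i theta} = sum(w e^{i phi}) / sum(w); unit weights when
    ``weights`` is None.
    """
    phi = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if phi.size == 0:
        raise ValueError("mean_vector requires at least one angle")
    if weights is None:
        w = np.ones_like(phi)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != phi.shape:
            raise ValueError("weights must match angles in shape")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(w > 0):
            raise ValueError("weights must not be all zero")
    z = np.sum(w * np.exp(1j * phi)) / np.sum(w)
    r = min(float(np.abs(z)), 1.0)
    theta = float(np.rad2deg(np.angle(z))) % 360.0
    if r <= 1e-12:
        theta = 0.0  # undefined; flagged via MeanVector.defined
    return MeanVector(length=r, angle_deg=theta)


def angular_deviation(arg) -> float:
    """Angular deviation s = sqrt(2(1 - R)), in degrees.

    Accepts a :class:`MeanVector` or a sequence of angles in degrees.
    """
    if isinstance(arg, MeanVector):
        r = arg.length
    else:
        r = mean_vector(arg).length
    return float(np.rad2deg(np.sqrt(2.0 * (1.0 - r))))


def _resultant_xy(angles_rad: np.ndarray) -> np.ndarray:
    """Cartesian mean resultant vector(s); works on the last axis."""
    return np.stack(
        [np.cos(angles_rad).mean(axis=-1), np.sin(angles_rad).mean(axis=-1)],
        axis=-1,
    )


def angular_permutation_test(
    group_a_deg,
    group_b_deg,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Two-sample test on angular distributions.

    The statistic is the Euclidean distance between the two groups'
    mean resultant vectors (unit weight per sample). Group labels are
    shuffled ``n_perm`` times; the returned p-value uses the add-one
    convention p = (1 + #{D_perm >= D_real}) / (1 + n_perm), with ties
    counted toward the null.
    """
    a = np.deg2rad(np.asarray(group_a_deg, dtype=float)).ravel()
    b = np.deg2rad(np.asarray(group_b_deg, dtype=float)).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d_real = float(np.linalg.norm(_resultant_xy(a) - _resultant_xy(b)))

    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    # one (n_perm, n) block of shuffled indices; argsort of uniforms is an
    # unbiased permutation per row
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pooled[order]
    va = _resultant_xy(shuffled[:, :n_a])
    vb = _resultant_xy(shuffled[:, n_a:])
    d_perm = np.linalg.norm(va - vb, axis=1)
    return float((1 + np.count_nonzero(d_perm >= d_real)) / (1 + n_perm))


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: min(1, p * m).

    ``m`` defaults to the number of tests and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    n_tests = p.size if p.ndim else 1
    if m is None:
        m = n_tests
    if m < n_tests:
        raise ValueError(f"m={m} smaller than the number of tests ({n_tests})")
    adjusted = np.minimum(1.0, p * m)
    return float(adjusted) if np.ndim(p_values) == 0 else adjusted
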