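"""Paired permutation tests for baseline vs follow-up comparisons.

The null hypothesis is that a participant's two assessment values are
exchangeable: within each participant the baseline/follow-up labels can be
swapped without changing the joint distribution. Swapping the labels of a
pair is equivalent to flipping the sign of its paired difference, so the
permutation group is the 2^n sign assignments. The test statistic is the
difference of assessment means, T = mean(FU) - mean(BL) = mean of the paired
differences.

Two implementations are provided: a seeded Monte Carlo sampler of the group
(the routine used on real data, default 100,000 iterations) and a full 2^n
enumeration usable up to n = 22 that serves as its exact oracle. The Monte
Carlo p-value uses the add-one convention p = (1 + b) / (1 + m), which keeps
the test valid (p > 0 and exact level control) regardless of m.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "PairedMatrix",
    "PermutationResult",
    "paired_permutation_test",
    "exact_sign_flip_test",
    "EXACT_ENUMERATION_LIMIT",
]

#: Largest n for which full 2^n enumeration is attempted.
EXACT_ENUMERATION_LIMIT = 22


@dataclass(frozen=True)
class PairedMatrix:
    """Complete n x 2 matrix of one variable at baseline (column 0) and
    follow-up (column 1), one row per participant."""

    values: np.ndarray
    participant_ids: Optional[tuple] = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 2:
            raise ValueError(f"paired data must be n x 2, got shape {values.shape}")
        if values.shape[0] < 1:
            raise ValueError("need at least 1 complete pair")
        if not np.isfinite(values).all():
            raise ValueError(
                "incomplete pairs: paired tests require a finite baseline and "
                "follow-up value for every participant (drop incomplete rows first)"
            )
        object.__setattr__(self, "values", values)
        if self.participant_ids is not None:
            ids = tuple(self.participant_ids)
            if len(ids) != values.shape[0]:
                raise ValueError("participant_ids length does not match row count")
            object.__setattr__(self, "participant_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def differences(self) -> np.ndarray:
        """Follow-up minus baseline, per participant."""
        return self.values[:, 1] - self.values[:, 0]


def as_paired_matrix(data: Union[PairedMatrix, Sequence, np.ndarray]) -> PairedMatrix:
    if isinstance(data, PairedMatrix):
        return data
    return PairedMatrix(np.asarray(data, dtype=float))


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a paired permutation test."""

    observed_statistic: float
    p_value: float
    iterations: int
    method: str  # "monte_carlo" | "exact"
    seed: Optional[int] = None
    n: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def paired_permutation_test(
    data: Union[PairedMatrix, Sequence, np.ndarray],
    iterations: int = 100_000,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> PermutationResult:
    """Monte Carlo permutation test for paired data.

    Each iteration independently swaps every participant's pair with
    probability 1/2 (uniform over the within-pair permutation group) and
    recomputes the difference of assessment means. Two-sided p-value with
    the add-one correction: (1 + #{|T_perm| >= |T_obs|}) / (1 + iterations).
    """
    data = as_paired_matrix(data)
    if data.n < 2:
        raise ValueError("the Monte Carlo test needs at least 2 pairs")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = data.differences
    t_obs = d.mean()
    abs_obs = abs(t_obs)

    hits = 0
    chunk = max(1, min(iterations, 2**22 // max(data.n, 1)))
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        signs = rng.integers(0, 2, size=(m, data.n)) * 2 - 1
        t_perm = (signs * d).mean(axis=1)
        hits += int(np.count_nonzero(np.abs(t_perm) >= abs_obs))
        done += m
    p = (1 + hits) / (1 + iterations)
    return PermutationResult(
        observed_statistic=float(t_obs),
        p_value=float(p),
        iterations=iterations,
        method="monte_carlo",
        seed=seed if isinstance(seed, int) else None,
        n=data.n,
    )


def exact_sign_flip_test(
    data: Union[PairedMatrix, Sequence, np.ndarray]
) -> PermutationResult:
    """Exact paired permutation test by full 2^n sign-flip enumeration.

    Enumerates every within-pair swap assignment; the two-sided p-value is
    the exact fraction of assignments with |T| >= |T_obs| (always >= 1/2^n
    because the identity assignment is included). Limited to
    n <= EXACT_ENUMERATION_LIMIT; use the Monte Carlo test beyond that.
    """
    data = as_paired_matrix(data)
    n = data.n
    if n > EXACT_ENUMERATION_LIMIT:
        raise ValueError(
            f"exact enumeration is limited to n <= {EXACT_ENUMERATION_LIMIT} "
            f"(2^{n} assignments); use paired_permutation_test instead"
        )
    d = data.differences
    t_obs = d.mean()
    abs_obs = abs(t_obs)
    total = 1 << n
    bit_positions = np.arange(n, dtype=np.uint32)
    hits = 0
    chunk = 1 << 18
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.uint32)
        bits = (idx[:, None] >> bit_positions) & 1  # 0/1 per pair
        signs = bits.astype(np.int8) * 2 - 1
        t_perm = (signs * d).mean(axis=1)
        hits += int(np.count_nonzero(np.abs(t_perm) >= abs_obs))
    return PermutationResult(
        observed_statistic=float(t_obs),
        p_value=hits / total,
        iterations=total,
        method="exact",
        n=n,
    )
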