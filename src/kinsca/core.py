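"""Conservation (ΔE) and statistical coupling (ΔΔE) over an anchored MSA.

The two statistics follow the sequence-based statistical coupling analysis of
Lockless & Ranganathan.  Per column i, the observed count of each amino acid x
(out of the column's non-gap depth n_i) is scored by a binomial probability at
the background rate q_x, and compared with the probability of the count implied
by the alignment-wide frequency of x at the same depth:

    ΔE_i = sqrt( Σ_x [ ln P_i^x − ln P_MSA^x ]² )

A *perturbation* at site j restricts the alignment to the sequences carrying a
fixed residue (the anchor protein's residue) at j.  The coupling of site i to
that perturbation is the magnitude of the change in the per-column log-ratio
vector between the subset alignment and the full alignment:

    ΔΔE_{i,j} = sqrt( Σ_x [ (ln P_{i|sub}^x − ln P_{MSA|sub}^x)
                            − (ln P_i^x − ln P_MSA^x) ]² )

Both quantities carry the arbitrary energy unit kT*, taken as 1 and omitted.
All log-probabilities are evaluated in log space (log-gamma), so the statistics
stay finite for any alignment depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .alignment import AA_ALPHABET, AA_INDEX, Alignment, counts_matrix
from .background import BackgroundFrequencies

__all__ = [
    "ConservationProfile",
    "PerturbationSpec",
    "CouplingMatrix",
    "binomial_log_prob",
    "delta_E",
    "conservation_profile",
    "perturbation_subset",
    "delta_delta_E",
    "full_coupling_matrix",
    "SMALL_SUBSET_WARNING",
]

#: Subsets smaller than this raise a warning (the statistic is still computed;
#: moderately conserved sites with ~35% subsets are a designed use case).
SMALL_SUBSET_WARNING = 20


class SmallSubsetWarning(UserWarning):
    pass


def binomial_log_prob(count: int, n: int, q: float) -> float:
    """ln of the binomial PMF, C(n,count) q^count (1-q)^(n-count), via log-gamma.

    Finite for every valid input; the degenerate n == 0, count == 0 case is the
    empty product with probability 1 (log 0.0).
    """
    if not (0 <= count <= n):
        raise ValueError(f"count must satisfy 0 <= count <= n, got count={count}, n={n}")
    if not (0.0 < q < 1.0):
        raise ValueError(f"background rate must lie in (0, 1), got {q}")
    if n == 0:
        return 0.0
    return float(binom.logpmf(count, n, q))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round ties-to-even would make the reference count depend on parity;
    # counts are non-negative so half-up == half-away-from-zero.
    return np.floor(x + 0.5).astype(np.int64)


def _log_ratio_vectors(
    counts: np.ndarray, n_eff: np.ndarray, bg: BackgroundFrequencies
) -> np.ndarray:
    """Per-column 20-vectors ln P_obs − ln P_ref; rows with n_eff == 0 are NaN.

    ``counts`` has shape (..., L, 20) and ``n_eff`` shape (..., L); the global
    (alignment-wide) frequency is computed over the same leading axes, so the
    subset variant reuses this routine with its own counts.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_eff = np.asarray(n_eff, dtype=np.int64)
    total = counts.sum(axis=(-2, -1), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        global_freq = counts.sum(axis=-2, keepdims=True) / np.where(total == 0, 1, total)
    ref_counts = _round_half_up(n_eff[..., None] * global_freq)
    q = bg.freq.reshape((1,) * (counts.ndim - 1) + (20,))
    n = n_eff[..., None]
    with np.errstate(invalid="ignore", divide="ignore"):
        lp_obs = binom.logpmf(counts, np.maximum(n, 1), q)
        lp_ref = binom.logpmf(ref_counts, np.maximum(n, 1), q)
    out = lp_obs - lp_ref
    out = np.where(n == 0, np.nan, out)
    return out


@dataclass(frozen=True)
class ConservationProfile:
    """ΔE per retained column, with the anchor protein's residue numbering."""

    delta_E: np.ndarray
    anchor_residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.delta_E) != len(self.anchor_residue_numbers):
            raise ValueError("profile and numbering differ in length")

    @property
    def normalized_percent(self) -> np.ndarray:
        """ΔE rescaled so the maximum is exactly 100 (all zeros stay zero)."""
        top = float(np.nanmax(self.delta_E)) if len(self.delta_E) else 0.0
        if top <= 0:
            return np.zeros_like(self.delta_E)
        return 100.0 * self.delta_E / top

    def at(self, residue_number: int) -> float:
        return float(self.delta_E[self.anchor_residue_numbers.index(residue_number)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.anchor_residue_numbers,
                "delta_E": self.delta_E,
                "percent_of_max": self.normalized_percent,
            }
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """An in-silico perturbation: fix residue_x at retained column site_j."""

    site_j: int
    residue_x: str
    subset_size: int
    n_effective_at_site: int
    anchor_residue_number: int | None = None

    def __post_init__(self) -> None:
        if self.residue_x not in AA_INDEX:
            raise ValueError(f"residue_x must be one of the 20 amino acids, got {self.residue_x!r}")
        if self.subset_size < 0 or self.subset_size > self.n_effective_at_site:
            raise ValueError("subset_size must lie in [0, n_effective_at_site]")

    @property
    def conservation_percent(self) -> float:
        """Subset size as a percent of the non-gap sequences at the site."""
        if self.n_effective_at_site == 0:
            return 0.0
        return 100.0 * self.subset_size / self.n_effective_at_site


@dataclass(frozen=True)
class CouplingMatrix:
    """L×L ΔΔE array: entry (i, j) is the effect on position i of perturbing j.

    Columns are perturbations, rows are affected positions (heat-map
    orientation).  Diagonal entries are self-couplings, computed but excluded
    from rankings and averages.  NaN marks undefined entries (position i all
    gaps within perturbation j's subset); ``column_defined`` is False for
    perturbations whose subset was empty, whose whole column is NaN.
    """

    ddE: np.ndarray
    anchor_residue_numbers: tuple[int, ...]
    perturbations: tuple[PerturbationSpec, ...]
    column_defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        L = len(self.anchor_residue_numbers)
        if self.ddE.shape != (L, L):
            raise ValueError(f"ddE must be {L}x{L}, got {self.ddE.shape}")
        if self.column_defined is None:
            object.__setattr__(self, "column_defined", ~np.all(np.isnan(self.ddE), axis=0))

    @property
    def n_positions(self) -> int:
        return len(self.anchor_residue_numbers)

    def index_of(self, residue_number: int) -> int:
        try:
            return self.anchor_residue_numbers.index(residue_number)
        except ValueError:
            raise KeyError(f"residue {residue_number} not in coupling matrix") from None

    def value(self, affected_residue: int, perturbed_residue: int) -> float:
        return float(self.ddE[self.index_of(affected_residue), self.index_of(perturbed_residue)])

    def column_mean(self, perturbed_residue: int) -> float:
        """Mean ΔΔE over all affected positions for one perturbation.

        The self-coupling diagonal entry and undefined (NaN) entries are
        excluded.
        """
        j = self.index_of(perturbed_residue)
        col = self.ddE[:, j].copy()
        col[j] = np.nan
        if np.all(np.isnan(col)):
            raise ValueError(f"perturbation at residue {perturbed_residue} is undefined")
        return float(np.nanmean(col))

    def to_frame(self) -> pd.DataFrame:
        nums = list(self.anchor_residue_numbers)
        return pd.DataFrame(self.ddE, index=nums, columns=nums)

    def to_tsv(self, path, float_format: str = "%.6g") -> None:
        df = self.to_frame()
        df.index.name = "affected\\perturbed"
        df.to_csv(path, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# Operations


def delta_E(aln: Alignment, column: int, bg: BackgroundFrequencies) -> float:
    """Conservation value of one column (root-sum-square of the 20 log-ratios)."""
    counts, n_eff = counts_matrix(aln)
    if not (0 <= column < aln.n_columns):
        raise IndexError(f"column {column} out of range")
    if n_eff[column] == 0:
        raise ValueError(f"column {column} has no non-gap characters; ΔE undefined")
    R = _log_ratio_vectors(counts, n_eff, bg)
    return float(np.sqrt(np.sum(R[column] ** 2)))


def conservation_profile(
    aln: Alignment,
    bg: BackgroundFrequencies,
    anchor_residue_numbers: tuple[int, ...] | None = None,
) -> ConservationProfile:
    """ΔE for every column of an anchor-reduced alignment."""
    counts, n_eff = counts_matrix(aln)
    if np.any(n_eff == 0):
        bad = int(np.argmax(n_eff == 0))
        raise ValueError(f"column {bad} has no non-gap characters; reduce or drop it first")
    R = _log_ratio_vectors(counts, n_eff, bg)
    values = np.sqrt(np.sum(R**2, axis=1))
    if anchor_residue_numbers is None:
        anchor_residue_numbers = tuple(range(aln.n_columns))
    return ConservationProfile(delta_E=values, anchor_residue_numbers=tuple(anchor_residue_numbers))


def perturbation_subset(
    aln: Alignment, site_j: int, residue_x: str, anchor_residue_number: int | None = None
) -> tuple[Alignment, PerturbationSpec]:
    """Rows of the alignment carrying ``residue_x`` at column ``site_j``."""
    if not (0 <= site_j < aln.n_columns):
        raise IndexError(f"site {site_j} out of range")
    if residue_x not in AA_INDEX:
        raise ValueError(f"residue must be one of the 20 amino acids, got {residue_x!r}")
    col = aln.to_indices()[:, site_j]
    keep = np.nonzero(col == AA_INDEX[residue_x])[0]
    if keep.size == 0:
        raise ValueError(
            f"no sequence carries {residue_x!r} at column {site_j}; perturbation undefined"
        )
    n_eff = int((col >= 0).sum())
    spec = PerturbationSpec(
        site_j=site_j,
        residue_x=residue_x,
        subset_size=int(keep.size),
        n_effective_at_site=n_eff,
        anchor_residue_number=anchor_residue_number,
    )
    if spec.subset_size < SMALL_SUBSET_WARNING:
        warnings.warn(
            f"perturbation subset at column {site_j} has only {spec.subset_size} sequences",
            SmallSubsetWarning,
            stacklevel=2,
        )
    return aln.take_rows(keep.tolist()), spec


def delta_delta_E(
    aln: Alignment,
    site_i: int,
    perturbation: PerturbationSpec,
    bg: BackgroundFrequencies,
) -> float:
    """Coupling of position ``site_i`` to one perturbation.

    NaN is returned when position i carries no amino acid within the subset
    (undefined; callers exclude NaN from averages and rankings).
    """
    if not (0 <= site_i < aln.n_columns):
        raise IndexError(f"site {site_i} out of range")
    sub, _ = perturbation_subset(aln, perturbation.site_j, perturbation.residue_x)
    counts_full, neff_full = counts_matrix(aln)
    counts_sub, neff_sub = counts_matrix(sub)
    if neff_full[site_i] == 0:
        raise ValueError(f"column {site_i} has no non-gap characters in the full alignment")
    if neff_sub[site_i] == 0:
        return float("nan")
    R_full = _log_ratio_vectors(counts_full, neff_full, bg)
    R_sub = _log_ratio_vectors(counts_sub, neff_sub, bg)
    return float(np.sqrt(np.sum((R_sub[site_i] - R_full[site_i]) ** 2)))


def full_coupling_matrix(
    aln: Alignment,
    bg: BackgroundFrequencies,
    anchor_residue_numbers: tuple[int, ...] | None = None,
) -> CouplingMatrix:
    """ΔΔE for every (affected, perturbed) column pair of a reduced alignment.

    Every column j is perturbed at the anchor sequence's residue.  The
    computation is vectorised: subset counts for all perturbations at once via
    a boolean-mask × one-hot matrix product, then a single batched binomial
    log-PMF evaluation over the (perturbation, column, amino-acid) array.
    """
    idx = aln.to_indices()
    N, L = idx.shape
    anchor = idx[aln.anchor_index]
    if np.any(anchor < 0):
        raise ValueError("alignment must be anchor-reduced (no gaps in the anchor row)")

    counts_full, neff_full = counts_matrix(aln)
    if np.any(neff_full == 0):
        raise ValueError("every column must contain at least one amino acid")
    R_full = _log_ratio_vectors(counts_full, neff_full, bg)  # (L, 20)

    onehot = np.zeros((N, L * 20), dtype=np.float32)
    valid = idx >= 0
    flat = np.arange(L) * 20 + np.where(valid, idx, 0)
    onehot[np.arange(N)[:, None], flat] = valid.astype(np.float32)

    # masks[j] selects the sequences matching the anchor residue at column j
    masks = (idx == anchor[None, :]).T.astype(np.float32)  # (L, N)
    counts_sub = np.rint(masks @ onehot).astype(np.int64).reshape(L, L, 20)
    neff_sub = counts_sub.sum(axis=2)
    subset_sizes = np.rint(masks.sum(axis=1)).astype(np.int64)

    R_sub = _log_ratio_vectors(counts_sub, neff_sub, bg)  # (L_pert, L, 20)
    ddE = np.sqrt(np.nansum((R_sub - R_full[None, :, :]) ** 2, axis=2))
    ddE = np.where(np.all(np.isnan(R_sub), axis=2), np.nan, ddE)
    ddE = ddE.T  # rows = affected position i, columns = perturbation j

    if anchor_residue_numbers is None:
        anchor_residue_numbers = tuple(range(L))
    perturbations = tuple(
        PerturbationSpec(
            site_j=j,
            residue_x=AA_ALPHABET[anchor[j]],
            subset_size=int(subset_sizes[j]),
            n_effective_at_site=int(neff_full[j]),
            anchor_residue_number=anchor_residue_numbers[j],
        )
        for j in range(L)
    )
    return CouplingMatrix(
        ddE=ddE,
        anchor_residue_numbers=tuple(anchor_residue_numbers),
        perturbations=perturbations,
    )
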