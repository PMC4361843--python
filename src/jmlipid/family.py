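"""Family-wide positional aggregation and clustering propensity.

Aggregation across a receptor family answers two questions: where along the
20-residue JM segment do lipid contacts concentrate (per-position mean over
receptors), and how conserved is the residue chemistry at each position
(per-position class and amino-acid probabilities, a position-weight-matrix
style table). The clustering propensity condenses a whole trajectory into
one enrichment number per species, comparable across receptors, and its
correlation with net JM charge quantifies the electrostatic driving force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import DEFAULT_CONTACT_CUTOFF
from .errors import (
    EmptyInputError,
    InsufficientDataError,
    UnknownSpeciesError,
)
from .membrane import LeafletComposition
from .residues import CLASS_LABELS, RESIDUE_CLASSES, classify_residue
from .trajectory import Trajectory, as_trajectory_list

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(RESIDUE_CLASSES))


@dataclass
class FamilyProfile:
    """Per-JM-position statistics aggregated over a receptor set."""

    n_receptors: int
    mean_contacts: pd.DataFrame  # positions x species
    class_probability: pd.DataFrame  # positions x class labels
    aa_frequency: pd.DataFrame  # positions x 20 amino acids


def positional_mean_contacts(
    per_receptor_profiles: Sequence[pd.Series | np.ndarray],
) -> np.ndarray:
    """Family mean contacts per JM position.

    Each input profile is one receptor's per-position mean contacts per
    frame (positions 1..L); the family value at each position is the sum
    over receptors divided by the receptor count.
    """
    if len(per_receptor_profiles) == 0:
        raise EmptyInputError("no receptor profiles supplied")
    arrays = [np.asarray(p, dtype=float) for p in per_receptor_profiles]
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1 or arrays[0].ndim != 1:
        raise ValueError(f"profiles must be 1-D and equal length, got shapes {lengths}")
    return np.mean(arrays, axis=0)


def positional_residue_probability(
    jm_sequences: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position residue-class and amino-acid probabilities.

    Returns ``(class_probability, aa_frequency)`` DataFrames indexed by JM
    position 1..L. Class probabilities at each position sum to 1, as do the
    20-letter frequencies.
    """
    if len(jm_sequences) == 0:
        raise EmptyInputError("no JM sequences supplied")
    lengths = {len(s) for s in jm_sequences}
    if len(lengths) != 1:
        raise ValueError(f"JM sequences must share one length, got {sorted(lengths)}")
    (length,) = lengths
    n = len(jm_sequences)
    positions = list(range(1, length + 1))
    class_counts = pd.DataFrame(0.0, index=positions, columns=list(CLASS_LABELS))
    aa_counts = pd.DataFrame(0.0, index=positions, columns=list(AMINO_ACIDS))
    for seq in jm_sequences:
        for pos, aa in enumerate(seq.upper(), start=1):
            class_counts.loc[pos, classify_residue(aa)] += 1
            aa_counts.loc[pos, aa] += 1
    return class_counts / n, aa_counts / n


def build_family_profile(
    jm_sequences: Sequence[str],
    mean_contact_profiles: Mapping[str, Sequence[np.ndarray]] | None = None,
) -> FamilyProfile:
    """Assemble a :class:`FamilyProfile` from sequences and contact profiles.

    ``mean_contact_profiles`` maps species name to one per-position profile
    per receptor (same receptor order as ``jm_sequences``).
    """
    class_prob, aa_freq = positional_residue_probability(jm_sequences)
    positions = class_prob.index
    if mean_contact_profiles:
        mc = pd.DataFrame(
            {
                sp: positional_mean_contacts(profiles)
                for sp, profiles in mean_contact_profiles.items()
            },
            index=positions,
        )
    else:
        mc = pd.DataFrame(index=positions)
    return FamilyProfile(
        n_receptors=len(jm_sequences),
        mean_contacts=mc,
        class_probability=class_prob,
        aa_frequency=aa_freq,
    )


def clustering_propensity(
    trajs: Trajectory | Sequence[Trajectory],
    species: str,
    leaflet: LeafletComposition,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> float:
    """First-shell enrichment of a species relative to its leaflet fraction.

    Computed literally as the mean over frames of (beads of the species
    within ``cutoff`` of the protein / total beads of the species), divided
    by the species' leaflet mole fraction. Geometry sets the no-enrichment
    baseline (shell area over box area, divided by the fraction); values
    well above it indicate clustering.
    """
    frac = leaflet.fraction(species)
    if frac <= 0:
        raise UnknownSpeciesError(
            f"species {species!r} has zero fraction in the leaflet specification"
        )
    traj_list = as_trajectory_list(trajs)
    cutoff2 = cutoff * cutoff
    per_frame_fracs: list[np.ndarray] = []
    for traj in traj_list:
        if not traj.has_species(species):
            raise UnknownSpeciesError(f"species {species!r} absent from trajectory")
        pos = traj.lipid_xy[:, traj.species_mask(species), :]
        n_beads = pos.shape[1]
        delta = pos[:, :, None, :] - traj.anchors.xy[None, None, :, :]
        delta -= traj.box_edge * np.round(delta / traj.box_edge)
        d2 = np.sum(delta * delta, axis=-1).min(axis=2)
        per_frame_fracs.append(np.sum(d2 <= cutoff2, axis=1) / n_beads)
    mean_frac = float(np.concatenate(per_frame_fracs).mean())
    return mean_frac / frac


@dataclass(frozen=True)
class PropensityRecord:
    """One receptor's clustering propensity for one species."""

    receptor_id: str
    species: str
    propensity: float
    net_jm_charge: int

    def __post_init__(self) -> None:
        if self.propensity < 0:
            raise ValueError("propensity must be non-negative")


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation between clustering propensity and net JM charge."""

    coefficient: float
    p_value: float
    n_used: int
    species: str
    method: str
    degenerate: bool  # True when variance was zero (coefficient is NaN)


def charge_propensity_correlation(
    records: Sequence[PropensityRecord],
    species: str,
    method: str = "pearson",
    positive_charge_only: bool = True,
) -> CorrelationResult:
    """Correlate clustering propensity with net JM charge across receptors.

    By default only receptors with net positive JM charge enter the
    statistic. With constant propensity or charge the coefficient is
    undefined; the result is returned with NaN and ``degenerate=True``
    rather than raising.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 usable records remain after filtering.
    """
    usable = [r for r in records if r.species == species]
    if positive_charge_only:
        usable = [r for r in usable if r.net_jm_charge > 0]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need >= 3 records for {species!r} "
            f"({'net-positive ' if positive_charge_only else ''}subset has {len(usable)})"
        )
    c = np.array([r.propensity for r in usable])
    q = np.array([r.net_jm_charge for r in usable], dtype=float)
    if np.ptp(c) == 0 or np.ptp(q) == 0:
        return CorrelationResult(
            coefficient=float("nan"), p_value=float("nan"), n_used=len(usable),
            species=species, method=method, degenerate=True,
        )
    if method == "pearson":
        res = stats.pearsonr(q, c)
    elif method == "spearman":
        res = stats.spearmanr(q, c)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        coefficient=float(res.statistic), p_value=float(res.pvalue),
        n_used=len(usable), species=species, method=method, degenerate=False,
    )


def saturation_breakpoint(
    records: Sequence[PropensityRecord],
    species: str,
) -> float:
    """Descriptive saturation charge for the propensity-vs-charge relation.

    Fits, for every candidate breakpoint b over the observed charge range,
    a rising segment below b and a flat segment at and above b (piecewise
    least squares) and returns the breakpoint with the smallest residual
    sum of squares. Purely descriptive; no inference is attached.
    """
    usable = sorted(
        (r for r in records if r.species == species and r.net_jm_charge > 0),
        key=lambda r: r.net_jm_charge,
    )
    if len(usable) < 4:
        raise InsufficientDataError("need >= 4 net-positive records for a breakpoint")
    q = np.array([r.net_jm_charge for r in usable], dtype=float)
    c = np.array([r.propensity for r in usable])
    charges = np.unique(q)
    best_b, best_rss = charges[-1], np.inf
    for b in charges[1:]:
        lo, hi = q < b, q >= b
        rss = 0.0
        if lo.sum() >= 2 and np.ptp(q[lo]) > 0:
            slope, icpt = np.polyfit(q[lo], c[lo], 1)
            rss += float(np.sum((c[lo] - (slope * q[lo] + icpt)) ** 2))
        else:
            rss += float(np.sum((c[lo] - c[lo].mean()) ** 2)) if lo.any() else 0.0
        rss += float(np.sum((c[hi] - c[hi].mean()) ** 2))
        if rss < best_rss:
            best_rss, best_b = rss, b
    return float(best_b)
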