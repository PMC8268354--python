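"""Mixture decomposition of composite Sanger chromatograms.

A chromatogram sequenced from a multi-copy gene family is, to a good
approximation, a linear superposition of the traces of the individual gene
copies: at every position each base channel carries signal proportional to
the number of template copies with that base there.  Given the candidate
haplotype sequences, the per-copy signal proportions can therefore be
recovered by non-negative least squares on a binary design matrix — one
column per haplotype, one row per (position, channel) cell.  An internal
deletion in one haplotype shifts all of its downstream bases relative to the
others, so every post-deletion position becomes a mixed peak and carries
information about the mixture; this is what makes the decomposition well
conditioned even for haplotypes that differ by only a few edits.

This module implements that decomposition plus the simpler single-site
peak-height-ratio estimator used when one informative SNP suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

CHANNELS = "ACGT"
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}


class DecompositionError(ValueError):
    """Raised when a trace or signature matrix cannot be decomposed."""


@dataclass
class Chromatogram:
    """Four-channel peak heights over a window of positions.

    heights: (n_positions, 4) non-negative array, columns ordered A, C, G, T.
    anchor: 1-based coordinate of the first row in the haplotype frame.
    annotations: optional named informative sites (name -> 1-based coordinate).
    """

    heights: np.ndarray
    anchor: int = 1
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[1] != 4:
            raise ValueError("heights must be an (n, 4) array ordered A,C,G,T")
        if self.heights.shape[0] == 0:
            raise ValueError("empty trace window")
        if np.any(self.heights < 0):
            raise ValueError("peak heights must be non-negative")
        if not np.any(self.heights > 0):
            raise ValueError("trace has no positive row")
        if self.anchor < 1:
            raise ValueError("anchor coordinate is 1-based")

    @property
    def n_positions(self) -> int:
        return int(self.heights.shape[0])


@dataclass
class SignatureMatrix:
    """Binary design matrix for trace decomposition.

    Rows are (position, channel) cells in position-major order; columns are
    candidate haplotypes anchored at ``anchor``.  Haplotypes that are
    indistinguishable over the window (identical columns) are collected into
    ``groups`` and must be fitted as one component.
    """

    matrix: np.ndarray
    haplotype_ids: list[str]
    anchor: int
    window_length: int
    groups: list[list[int]]

    @property
    def has_unidentifiable(self) -> bool:
        return any(len(g) > 1 for g in self.groups)

    def group_labels(self) -> list[str]:
        return ["+".join(self.haplotype_ids[i] for i in g) for g in self.groups]


@dataclass
class MixtureEstimate:
    """Per-component signal proportions with fit quality."""

    proportions: dict[str, float]
    weights: dict[str, float]
    r_squared: float
    method: str = "nnls"

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total!r}")
        if any(v < -1e-12 for v in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def _windowed_sequence(sequence: str, hap_id: str, anchor: int, length: int) -> str:
    end = anchor - 1 + length
    if anchor < 1:
        raise ValueError("anchor coordinate is 1-based")
    if end > len(sequence):
        raise DecompositionError(
            f"window [{anchor}, {end}] extends past the shifted end of "
            f"haplotype {hap_id!r} (length {len(sequence)})"
        )
    return sequence[anchor - 1 : end].upper()


def build_signatures(haplotypes: Sequence, anchor: int, window_length: int) -> SignatureMatrix:
    """Build the binary (position x channel) design matrix for a haplotype set.

    Haplotypes are anchored at the window start, so a haplotype carrying an
    internal deletion contributes its post-deletion bases shifted upstream —
    exactly as they appear in the physical trace.  Bases outside ACGT (e.g. N)
    contribute no signal.
    """
    if window_length < 1:
        raise ValueError("window_length must be positive")
    if not haplotypes:
        raise ValueError("at least one haplotype is required")
    n = len(haplotypes)
    mat = np.zeros((window_length * 4, n), dtype=np.uint8)
    ids = []
    for j, hap in enumerate(haplotypes):
        seq = hap.sequence if hasattr(hap, "sequence") else str(hap)
        hap_id = getattr(hap, "id", f"hap{j}")
        ids.append(hap_id)
        window = _windowed_sequence(seq, hap_id, anchor, window_length)
        for i, base in enumerate(window):
            k = _CHANNEL_INDEX.get(base)
            if k is not None:
                mat[i * 4 + k, j] = 1
    seen: dict[bytes, int] = {}
    groups: list[list[int]] = []
    for j in range(n):
        key = mat[:, j].tobytes()
        if key in seen:
            groups[seen[key]].append(j)
        else:
            seen[key] = len(groups)
            groups.append([j])
    return SignatureMatrix(mat, ids, anchor, window_length, groups)


def decompose(trace: Chromatogram, signatures: SignatureMatrix,
              merge_identical: bool = True) -> MixtureEstimate:
    """Non-negative least-squares fit of a trace on haplotype signatures.

    Returns proportions normalised to sum to one; components that are
    indistinguishable over the window are merged into a single group (their
    reported proportion is the group total).  ``r_squared`` is 1 - SSR/SST on
    the flattened (position x channel) response.
    """
    y = trace.heights.ravel()
    if trace.n_positions * 4 != signatures.matrix.shape[0]:
        raise DecompositionError(
            f"trace has {trace.n_positions} positions but signatures cover "
            f"{signatures.matrix.shape[0] // 4}"
        )
    if not np.any(y > 0):
        raise DecompositionError("all-zero trace cannot be decomposed")
    if signatures.has_unidentifiable and not merge_identical:
        raise DecompositionError(
            "signature matrix has identical columns; merge identical columns "
            "(merge_identical=True) to fit the groups jointly"
        )
    design = np.column_stack(
        [signatures.matrix[:, g[0]].astype(float) for g in signatures.groups]
    )
    weights, _ = nnls(design, y)
    total = float(weights.sum())
    if total <= 0:
        raise DecompositionError("degenerate fit: all component weights are zero")
    ssr = float(np.sum((y - design @ weights) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 and ssr <= 1e-12 else 1.0 - ssr / sst if sst > 0 else 0.0
    r2 = min(1.0, max(0.0, r2))
    labels = signatures.group_labels()
    return MixtureEstimate(
        proportions={lab: float(w / total) for lab, w in zip(labels, weights)},
        weights={lab: float(w) for lab, w in zip(labels, weights)},
        r_squared=r2,
        method="nnls",
    )


def combine_orientations(estimate_f: MixtureEstimate,
                         estimate_r: MixtureEstimate) -> MixtureEstimate:
    """Average forward- and reverse-orientation estimates.

    Proportions are combined by unweighted mean per component; the reported
    fit quality is the more pessimistic of the two orientations.
    """
    if set(estimate_f.proportions) != set(estimate_r.proportions):
        raise ValueError("orientation estimates cover different haplotype sets")
    if estimate_f.method != estimate_r.method:
        raise ValueError("orientation estimates use different methods")
    props = {
        k: 0.5 * (estimate_f.proportions[k] + estimate_r.proportions[k])
        for k in estimate_f.proportions
    }
    weights = {
        k: 0.5 * (estimate_f.weights.get(k, 0.0) + estimate_r.weights.get(k, 0.0))
        for k in estimate_f.proportions
    }
    return MixtureEstimate(
        proportions=props,
        weights=weights,
        r_squared=min(estimate_f.r_squared, estimate_r.r_squared),
        method=estimate_f.method,
    )


def peak_ratio(trace: Chromatogram, site: int, alleles: Sequence[str]) -> dict[str, float]:
    """Single-site allele proportions from channel peak heights.

    ``site`` is a 1-based coordinate in the trace's anchor frame; ``alleles``
    lists the base channels segregating there (e.g. ["C", "T"]).  Returns the
    height of each listed channel divided by their sum.
    """
    if len(alleles) < 2:
        raise ValueError("at least two allele channels are required")
    row = site - trace.anchor
    if not (0 <= row < trace.n_positions):
        raise ValueError(f"site {site} lies outside the trace window")
    bad = [a for a in alleles if a.upper() not in _CHANNEL_INDEX]
    if bad:
        raise ValueError(f"unknown channels: {bad}")
    heights = [float(trace.heights[row, _CHANNEL_INDEX[a.upper()]]) for a in alleles]
    total = sum(heights)
    if total <= 0:
        raise DecompositionError(f"zero total height at site {site}")
    return {a.upper(): h / total for a, h in zip(alleles, heights)}
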