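"""Synthetic data generators for the WZ/ZZ copy-number analysis pipeline.

Everything the downstream stages consume can be generated here with known
ground truth: multi-copy haplotype families with a W-specific variant,
composite Sanger chromatograms whose minor-copy signal fraction is set by
integer copy numbers (1/3, 1/4, 1/5 ...), case-control cohorts sampled by
phenotypic sex under a female-heterogametic (WZ female / ZZ male) model with
marker recombination and rare sex reversal, and short-read libraries with an
exact number of planted 32-mer probe occurrences.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracedecomp import Chromatogram, build_signatures

BASES = "ACGT"


class ParameterError(ValueError):
    """Raised when simulation parameters are inconsistent or infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs shared across generators.

    noise_cv is the coefficient of variation of multiplicative peak-height
    noise (dimensionless); gain is the mean peak height contributed by one
    template copy, in arbitrary signal units.
    """

    seed: int = 0
    n_females: int = 48
    n_males: int = 48
    recomb_fraction: float = 0.0
    sex_reversal_rate: float = 0.0
    noise_cv: float = 0.05
    gain: float = 100.0
    read_length: int = 100
    library_size: int = 10_000

    def __post_init__(self) -> None:
        for name in ("recomb_fraction", "sex_reversal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.gain <= 0:
            raise ParameterError("gain must be positive")
        if self.library_size < 0:
            raise ParameterError("library_size must be >= 0")
        if self.n_females < 0 or self.n_males < 0:
            raise ParameterError("cohort sizes must be >= 0")


@dataclass
class Haplotype:
    """A named gene-copy sequence with its chromosome of residence."""

    id: str
    sequence: str
    chromosome: str  # "W" or "Z"
    role: str = "other"  # banf2a | banf2b | banf2c | banf2w | other
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("haplotype sequence must be non-empty")
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set(BASES + "N"):
            raise ValueError("haplotype alphabet is ACGTN")
        if self.chromosome not in ("W", "Z"):
            raise ValueError("chromosome must be W or Z")
        if self.role == "banf2w" and self.chromosome != "W":
            raise ValueError("banf2w is W-linked by definition")


@dataclass(frozen=True)
class MarkerDef:
    """A genetic marker with its map position and linkage to the SD locus.

    recomb_fraction is the per-gamete probability that the marker allele
    recombines away from the sex-determining allele; dominant markers are
    scored as presence/absence of ``dominant_allele``.
    """

    name: str
    position_kbp: float
    recomb_fraction: float = 0.0
    dominant: bool = False
    dominant_allele: str = "W"

    def __post_init__(self) -> None:
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ParameterError("marker recomb_fraction must lie in [0, 0.5]")


_Z_ROLE_ORDER = ("banf2a", "banf2b")


def gen_haplotype_set(base_length: int, n_z_copies: int, include_w_variant: bool,
                      indel_length: int, n_substitutions: int, seed: int) -> list[Haplotype]:
    """Generate a gene-copy family: identical Z copies plus one W variant.

    The Z-linked copies are verbatim duplicates of one random base sequence
    (they represent tandem gene duplicates).  The W variant, when requested,
    differs from that template by exactly ``n_substitutions`` substitutions
    and one internal deletion of ``indel_length`` bases; edit coordinates are
    recorded in the haplotype annotations (1-based, template frame).
    """
    if base_length < 60:
        raise ParameterError("base_length must be >= 60")
    if n_z_copies < 1:
        raise ParameterError("need at least one Z copy")
    if indel_length < 0 or n_substitutions < 0:
        raise ParameterError("edit counts must be >= 0")
    # edits are kept 10 bases clear of both ends so windows anchor cleanly
    margin = 10
    if include_w_variant and base_length - 2 * margin < indel_length + n_substitutions:
        raise ParameterError(
            f"base_length {base_length} too small to place {n_substitutions} "
            f"substitutions and a {indel_length}-base deletion"
        )
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(BASES), size=base_length))
    haps: list[Haplotype] = []
    for i in range(n_z_copies):
        role = _Z_ROLE_ORDER[i] if i < len(_Z_ROLE_ORDER) else "other"
        hap_id = role if i < len(_Z_ROLE_ORDER) else f"banf2z{i + 1}"
        haps.append(Haplotype(hap_id, base, "Z", role))
    if include_w_variant:
        seq = list(base)
        del_start = 0
        if indel_length > 0:
            del_start = int(rng.integers(margin, base_length - margin - indel_length + 1))
        deleted = set(range(del_start, del_start + indel_length))
        candidates = [p for p in range(margin, base_length - margin) if p not in deleted]
        sub_positions = sorted(
            int(p) for p in rng.choice(candidates, size=n_substitutions, replace=False)
        ) if n_substitutions else []
        subs = []
        for p in sub_positions:
            ref = seq[p]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            seq[p] = alt
            subs.append((p + 1, ref, alt))
        if indel_length > 0:
            seq = seq[:del_start] + seq[del_start + indel_length:]
        ann = {"substitutions": subs}
        if indel_length > 0:
            ann["deletion"] = (del_start + 1, indel_length)
        haps.append(Haplotype("banf2w", "".join(seq), "W", "banf2w", ann))
    return haps


def gen_trace(haplotypes: Sequence[Haplotype], copy_numbers: Sequence[int],
              window: tuple[int, int], noise_cv: float, gain: float,
              seed: int) -> Chromatogram:
    """Synthesize a composite chromatogram from copy-weighted haplotypes.

    ``window`` is a 1-based inclusive (start, end) interval; every haplotype
    is anchored at the window start, so an internal deletion shifts all of a
    haplotype's downstream bases, producing the mixed post-deletion peaks
    seen in real composite traces.  Heights are gain x copy-weighted base
    indicators, perturbed by multiplicative Gaussian noise of the stated CV
    and truncated at zero; noise_cv = 0 gives a deterministic trace.
    """
    if len(copy_numbers) != len(haplotypes):
        raise ParameterError("copy_numbers must align 1:1 with haplotypes")
    copies = np.asarray(copy_numbers, dtype=float)
    if np.any(copies < 0) or not np.any(copies > 0):
        raise ParameterError("copy numbers must be >= 0 with at least one > 0")
    start, end = window
    length = end - start + 1
    if length < 1:
        raise ParameterError("empty trace window")
    sig = build_signatures(haplotypes, start, length)
    heights = (sig.matrix.astype(float) @ (gain * copies)).reshape(length, 4)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        heights = heights * (1.0 + rng.normal(0.0, noise_cv, size=heights.shape))
        heights = np.clip(heights, 0.0, None)
    return Chromatogram(heights, anchor=start)


def gen_cohort(config: SimConfig, markers: Sequence[MarkerDef]) -> pd.DataFrame:
    """Simulate a case-control cohort sampled by phenotypic sex.

    Each individual carries a latent sex-determining genotype (WZ for
    designated females, ZZ for males); the recorded phenotypic sex flips with
    probability ``sex_reversal_rate``.  Marker genotypes are inherited from
    the SD genotype with each marker's recombination fraction applied
    independently per transmitted chromosome.  Truth columns are retained so
    parameter recovery can be tested.
    """
    if config.n_females + config.n_males == 0:
        raise ParameterError("cohort must contain at least one individual")
    rng = np.random.default_rng(config.seed)
    rows = []
    designs = [("F", "WZ")] * config.n_females + [("M", "ZZ")] * config.n_males
    for idx, (design_sex, truth) in enumerate(designs, start=1):
        reversed_ = rng.random() < config.sex_reversal_rate
        sex = {"F": "M", "M": "F"}[design_sex] if reversed_ else design_sex
        row = {"id": f"ind{idx:04d}", "sex": sex}
        for marker in markers:
            alleles = []
            for sd_allele in truth:
                flip = rng.random() < marker.recomb_fraction
                alleles.append({"W": "Z", "Z": "W"}[sd_allele] if flip else sd_allele)
            row[marker.name] = "".join(sorted(alleles))
        row["truth_sd"] = truth
        rows.append(row)
    cols = ["id", "sex", *[m.name for m in markers], "truth_sd"]
    return pd.DataFrame(rows, columns=cols)


def _random_read(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


_MAX_REJECT = 1000


def _sample_clean_read(rng: np.random.Generator, length: int,
                       forbidden: Sequence[str], embed: str | None = None) -> str:
    """Rejection-sample a read free of every forbidden k-mer.

    When ``embed`` is given, the read contains it verbatim at a random offset
    and is only checked against the other forbidden strings.
    """
    for _ in range(_MAX_REJECT):
        if embed is None:
            read = _random_read(rng, length)
            if not any(f in read for f in forbidden):
                return read
        else:
            offset = int(rng.integers(0, length - len(embed) + 1))
            read = (_random_read(rng, offset) + embed
                    + _random_read(rng, length - offset - len(embed)))
            if not any(f in read for f in forbidden if f != embed):
                return read
    raise ParameterError(
        "could not sample a read avoiding probe collisions; the read length "
        "is too small relative to the probe set"
    )


def gen_reads(transcripts: Sequence[tuple], read_length: int, library_size: int,
              seed: int, probe_length: int = 32) -> list[tuple[str, str]]:
    """Generate a read library with exact planted probe occurrences.

    ``transcripts`` is a list of (sequence, count) or (sequence, count, probe)
    tuples; the probe defaults to the transcript's first ``probe_length``
    bases.  ``count`` may be an int (forward-strand plants) or an
    (n_forward, n_revcomp) pair.  Exactly the requested number of reads
    contain each probe (or its reverse complement); background reads are
    rejection-sampled to contain no probe in either orientation, so planted
    counts are exact ground truth.  Returns (read_id, sequence) pairs.
    """
    if read_length < probe_length:
        raise ParameterError(f"read_length must be >= probe length {probe_length}")
    rng = np.random.default_rng(seed)
    plan = []  # (transcript index, probe, n_fwd, n_rc)
    for t_idx, entry in enumerate(transcripts):
        if len(entry) == 3:
            seq, count, probe = entry
        else:
            seq, count = entry
            if len(seq) < probe_length:
                raise ParameterError("transcript shorter than probe length")
            probe = seq[:probe_length].upper()
        probe = probe.upper()
        if set(probe) - set(BASES):
            raise ParameterError("probe alphabet is ACGT")
        n_fwd, n_rc = (count, 0) if isinstance(count, int) else tuple(count)
        plan.append((t_idx, probe, n_fwd, n_rc))
    total_planted = sum(f + r for _, _, f, r in plan)
    if total_planted > library_size:
        raise ParameterError("planted read counts exceed library_size")
    forbidden = []
    for _, probe, _, _ in plan:
        forbidden.extend([probe, _revcomp(probe)])
    reads = []
    for t_idx, probe, n_fwd, n_rc in plan:
        for k in range(n_fwd):
            reads.append((f"planted_t{t_idx}_f{k}",
                          _sample_clean_read(rng, read_length, forbidden, embed=probe)))
        for k in range(n_rc):
            reads.append((f"planted_t{t_idx}_r{k}",
                          _sample_clean_read(rng, read_length, forbidden,
                                             embed=_revcomp(probe))))
    for k in range(library_size - total_planted):
        reads.append((f"bg_{k}", _sample_clean_read(rng, read_length, forbidden)))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]
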