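"""Integer copy-ratio inference and per-chromosome gene-configuration models.

A decomposed trace yields the fraction of signal carried by the W-specific
gene copy; with two to five copies per diploid genome that fraction is close
to a small integer ratio (1/3, 1/4, 1/5 ...).  This module snaps an
estimated fraction to the best integer (major:minor) copy ratio, enumerates
the chromosome configurations consistent with it — which copies sit on the W
and which on the Z, with or without a Z-linked duplication — and classifies
an individual's copy model against its phenotypic sex, flagging discordant
cases (e.g. a phenotypic male carrying W-specific signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .tracedecomp import MixtureEstimate

W_ROLE = "banf2w"
W_LINKED_ROLES = ("banf2w", "banf2c")
Z_SINGLE = ("banf2a",)
Z_DUPLICATED = ("banf2a", "banf2b")

#: default ceiling on copies per diploid genome (two to five copies observed)
DEFAULT_MAX_TOTAL = 5
#: W-specific signal fraction above which an individual is called W-bearing;
#: halfway between noise and the smallest true fraction (1/5)
DEFAULT_W_THRESHOLD = 0.10


@dataclass(frozen=True)
class CopyRatio:
    """Integer (major, minor) copy counts.

    ``minor`` counts the distinguishable minor component — the W-specific
    copies in a female trace, or the duplicated Z copies at a male's
    informative SNP.
    """

    major: int
    minor: int

    def __post_init__(self) -> None:
        if self.major < 1 or self.minor < 1:
            raise ValueError("copy counts must be >= 1")

    @property
    def total(self) -> int:
        return self.major + self.minor

    @property
    def predicted_minor_fraction(self) -> float:
        return self.minor / self.total


@dataclass(frozen=True)
class ChromosomeModel:
    """Role assignment of gene copies to sex chromosomes."""

    sex_genotype: str  # WZ | ZZ | WW
    w_chromosomes: tuple[tuple[str, ...], ...]
    z_chromosomes: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if self.sex_genotype not in ("WZ", "ZZ", "WW"):
            raise ValueError("sex_genotype must be WZ, ZZ or WW")
        n_w = {"WZ": 1, "ZZ": 0, "WW": 2}[self.sex_genotype]
        if len(self.w_chromosomes) != n_w or len(self.z_chromosomes) != 2 - n_w:
            raise ValueError("chromosome count inconsistent with sex genotype")
        for chrom in self.z_chromosomes:
            if W_ROLE in chrom:
                raise ValueError("banf2w cannot reside on a Z chromosome")

    @property
    def w_copies(self) -> tuple[str, ...]:
        return tuple(r for chrom in self.w_chromosomes for r in chrom)

    @property
    def z_copies(self) -> tuple[str, ...]:
        return tuple(r for chrom in self.z_chromosomes for r in chrom)

    @property
    def total_copies(self) -> int:
        return len(self.w_copies) + len(self.z_copies)

    @property
    def w_specific_fraction(self) -> float:
        return self.w_copies.count(W_ROLE) / self.total_copies


def infer_copy_ratio(minor_fraction: float, max_total: int = DEFAULT_MAX_TOTAL) -> CopyRatio:
    """Snap an estimated minor-signal fraction to the best integer copy ratio.

    Searches all (major >= 1, minor >= 1) pairs with major + minor <=
    ``max_total`` for the one whose minor/total is closest to the estimate;
    ties break toward the smaller total, then the smaller minor count, so the
    returned ratio is always in lowest terms.
    """
    if not 0.0 < minor_fraction < 1.0:
        raise ValueError("minor_fraction must lie strictly in (0, 1)")
    if max_total < 2:
        raise ValueError("max_total must be >= 2")
    best: Optional[tuple] = None
    for total in range(2, max_total + 1):
        for minor in range(1, total):
            key = (abs(minor / total - minor_fraction), total, minor)
            if best is None or key < best:
                best = key
                best_pair = (total - minor, minor)
    return CopyRatio(*best_pair)


def enumerate_models(sex_genotype: str, total_copies: int, w_specific_copies: int,
                     z_duplication_allowed: bool) -> list[ChromosomeModel]:
    """Enumerate chromosome configurations matching the given copy counts.

    Each W chromosome carries the W-specific roles (banf2w, optionally
    banf2c); each Z carries one copy (banf2a) or, when a Z duplication is
    allowed, two (banf2a + banf2b).  Returns every configuration whose total
    copy count matches, in canonical order; an empty list means no
    configuration fits.
    """
    if sex_genotype not in ("WZ", "ZZ", "WW"):
        raise ValueError("sex_genotype must be WZ, ZZ or WW")
    if w_specific_copies > total_copies or w_specific_copies < 0:
        raise ValueError("w_specific_copies inconsistent with total_copies")
    if sex_genotype == "ZZ" and w_specific_copies != 0:
        raise ValueError("a ZZ individual carries no W-specific copies")
    n_w = {"WZ": 1, "ZZ": 0, "WW": 2}[sex_genotype]
    if n_w > 0:
        if w_specific_copies % n_w != 0:
            raise ValueError("w_specific_copies must split evenly across W chromosomes")
        per_w = w_specific_copies // n_w
        if per_w not in (1, 2):
            raise ValueError("each W chromosome carries one or two W-specific copies")
        w_roles = W_LINKED_ROLES[:per_w]
    else:
        w_roles = ()
    z_options = [Z_SINGLE] + ([Z_DUPLICATED] if z_duplication_allowed else [])
    models = []
    if sex_genotype == "ZZ":
        for i, z1 in enumerate(z_options):
            for z2 in z_options[i:]:
                if len(z1) + len(z2) == total_copies:
                    models.append(ChromosomeModel("ZZ", (), (z1, z2)))
    elif sex_genotype == "WZ":
        for z in z_options:
            if len(w_roles) + len(z) == total_copies:
                models.append(ChromosomeModel("WZ", (w_roles,), (z,)))
    else:  # WW
        if 2 * len(w_roles) == total_copies:
            models.append(ChromosomeModel("WW", (w_roles, w_roles), ()))
    models.sort(key=lambda m: (len(m.z_copies), m.z_chromosomes))
    return models


@dataclass
class Classification:
    """Outcome of classifying one individual's copy configuration."""

    sex: str
    sex_genotype: str
    ratio: Optional[CopyRatio]
    models: list[ChromosomeModel] = field(default_factory=list)
    concordant: bool = True
    w_fraction: float = 0.0


def _w_fraction(estimate: MixtureEstimate) -> float:
    return sum(p for label, p in estimate.proportions.items()
               if W_ROLE in label.split("+"))


def classify_individual(estimates: MixtureEstimate | Sequence[MixtureEstimate],
                        sex: str, *, dup_fraction: Optional[float] = None,
                        threshold: float = DEFAULT_W_THRESHOLD,
                        max_total: int = DEFAULT_MAX_TOTAL) -> Classification:
    """Infer an individual's copy ratio and chromosome model from estimates.

    The W-specific signal fraction (averaged over the supplied decomposition
    estimates) decides W-bearing status at ``threshold``.  W-bearing
    individuals get a WZ copy ratio and every consistent WZ configuration;
    others get a ZZ configuration whose Z-duplication status is resolved by
    ``dup_fraction``, the minor-allele fraction at the informative SNP (e.g.
    the C share of the C/T peak ratio).  The concordance flag is False when
    the genotype contradicts the phenotypic sex — the mechanism behind a
    near-perfect marker table's single mismatch.
    """
    if sex not in ("F", "M"):
        raise ValueError("sex must be F or M")
    ests = [estimates] if isinstance(estimates, MixtureEstimate) else list(estimates)
    if not ests:
        raise ValueError("at least one estimate is required")
    w_frac = sum(_w_fraction(e) for e in ests) / len(ests)
    if w_frac >= threshold:
        ratio = infer_copy_ratio(w_frac, max_total)
        models = []
        for w_specific in (1, 2):
            for dup in (False, True):
                for m in enumerate_models("WZ", ratio.total, w_specific, dup):
                    if m not in models and m.w_copies.count(W_ROLE) == ratio.minor:
                        models.append(m)
        # an empty model list (e.g. five total copies, which no W/Z role
        # assignment reaches) leaves the ratio reported but the chromosome
        # placement unresolved
        return Classification(sex, "WZ", ratio, models,
                              concordant=(sex == "F"), w_fraction=w_frac)
    # No W signal: ZZ.  The duplicated copy occurs only in tandem with the
    # original, so the informative-site minor fraction is constrained to
    # b/(2+b) for b duplicated copies in {0, 1, 2}; snap to the nearest.
    target = dup_fraction if dup_fraction is not None else 0.0
    b = min((0, 1, 2), key=lambda k: abs(k / (2 + k) - target))
    total = 2 + b
    ratio = CopyRatio(total - b, b) if b >= 1 else None
    models = [m for m in enumerate_models("ZZ", total, 0, True)
              if m.total_copies == total]
    return Classification(sex, "ZZ", ratio, models,
                          concordant=(sex == "M"), w_fraction=w_frac)
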