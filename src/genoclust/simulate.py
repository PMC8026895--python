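"""Synthetic block-structured identity matrices with known genospecies truth.

Every clustering stage is testable without downloads: a
:class:`GenospeciesTruth` declares species blocks and the within/between
identity ranges; :func:`make_block_matrix` draws a reproducible asymmetric
matrix from it.  Only the order relation of the values against the cutoff
matters to the method, so values are drawn uniformly within each range and
a small directional jitter (default ±0.2 percentage points) makes the raw
matrix asymmetric, exercising the pair-averaging step the way real
query/reference ANI output does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import LabeledMatrix

__all__ = ["GenospeciesTruth", "make_block_matrix", "make_labels", "default_truth"]

#: default directional jitter, percentage points
DEFAULT_JITTER = 0.2

LABEL_STYLES = ("binomial-strain", "quoted", "mixed")

# pools for generated organism names; products of genus x epithet are
# plausible-looking but deliberately not real binomials
_GENERA = (
    "Rhizomimus", "Agrofictus", "Bradyspurius", "Mesomimus", "Ensimulo",
    "Methylofictus", "Bartomimus", "Aminofictus", "Xanthomimus", "Aurantimimus",
)
_EPITHETS = (
    "simulatus", "fictus", "exemplaris", "arenarius", "pratensis",
    "lacustris", "collinus", "riparius", "silvaticus", "campestris",
)


@dataclass(frozen=True)
class GenospeciesTruth:
    """Ground truth for a synthetic genospecies matrix.

    ``species_blocks`` maps each species key to its member genome labels;
    within-block identities are drawn from ``within_range`` and
    between-block identities from ``between_range`` (percent).  Unless
    ``overlapping`` is set, the ranges must be separated
    (within.low > between.high) so a cutoff between them recovers the
    blocks exactly.
    """

    species_blocks: tuple[tuple[str, tuple[str, ...]], ...]
    within_range: tuple[float, float] = (96.0, 100.0)
    between_range: tuple[float, float] = (75.0, 85.0)
    seed: int = 0
    overlapping: bool = False

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (*self.within_range, "within_range"),
            (*self.between_range, "between_range"),
        ):
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 100")
        if not self.overlapping and self.within_range[0] <= self.between_range[1]:
            raise ValueError(
                "within_range.low must exceed between_range.high "
                "(or set overlapping=True)"
            )
        labels = self.all_labels
        if len(set(labels)) != len(labels):
            raise ValueError("member labels must be unique across blocks")
        if not labels:
            raise ValueError("at least one non-empty species block required")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return tuple(l for _, members in self.species_blocks for l in members)

    @property
    def blocks_as_sets(self) -> list[tuple[str, ...]]:
        """Blocks in the deterministic order cluster outputs use."""
        blocks = [tuple(sorted(members)) for _, members in self.species_blocks]
        blocks.sort(key=lambda b: (-len(b), b))
        return blocks


def default_truth(
    n_species: int = 4,
    block_size: int = 3,
    within_range: tuple[float, float] = (96.0, 100.0),
    between_range: tuple[float, float] = (75.0, 85.0),
    seed: int = 0,
    label_style: str = "binomial-strain",
) -> GenospeciesTruth:
    """Truth with ``n_species`` equal blocks and generated organism names."""
    labels = make_labels(n_species, block_size, style=label_style, seed=seed)
    blocks = []
    for k in range(n_species):
        members = tuple(labels[k * block_size: (k + 1) * block_size])
        blocks.append((f"species_{k}", members))
    return GenospeciesTruth(
        tuple(blocks), within_range, between_range, seed=seed
    )


def make_labels(
    n_species: int, block_size: int, style: str = "binomial-strain", seed: int = 0
) -> list[str]:
    """Generate organism-name labels in the naming styles real node labels use.

    ``binomial-strain``: ``Genus epithet STRAIN``; ``quoted``: the binomial
    wrapped in quotes with a type-strain marker (a not-validly-published
    name); ``mixed`` cycles binomial / quoted / ``sp.``-placeholder.
    """
    if style not in LABEL_STYLES:
        raise ValueError(f"style must be one of {LABEL_STYLES}, got {style!r}")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for k in range(n_species):
        genus = _GENERA[k % len(_GENERA)]
        epithet = _EPITHETS[(k // len(_GENERA)) % len(_EPITHETS)]
        if k >= len(_GENERA) * len(_EPITHETS):
            epithet = f"{epithet}{k}"
        # draw strain numbers without replacement so labels never collide
        numbers = rng.choice(np.arange(100, 99999), size=block_size, replace=False)
        for m in range(block_size):
            strain = f"DSM {numbers[m]}"
            if style == "quoted" or (style == "mixed" and m % 3 == 1):
                labels.append(f'"{genus} {epithet}" {strain}^T^')
            elif style == "mixed" and m % 3 == 2:
                labels.append(f"{genus} sp. {strain}")
            else:
                labels.append(f"{genus} {epithet} {strain}^T^")
    return labels


def make_block_matrix(
    truth: GenospeciesTruth, asymmetry_jitter: float = DEFAULT_JITTER
) -> tuple[LabeledMatrix, GenospeciesTruth]:
    """Draw a reproducible asymmetric identity matrix realizing ``truth``.

    Each unordered pair gets a base value from its block's range; the two
    directions then receive independent uniform(-jitter, +jitter) offsets,
    clipped to [0, 100].  The diagonal is 100.  Identical seeds yield
    identical matrices.
    """
    if asymmetry_jitter < 0:
        raise ValueError("asymmetry_jitter must be >= 0")
    labels = truth.all_labels
    block_of = {
        label: bi
        for bi, (_, members) in enumerate(truth.species_blocks)
        for label in members
    }
    rng = np.random.default_rng(truth.seed)
    n = len(labels)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = (
                truth.within_range
                if block_of[labels[i]] == block_of[labels[j]]
                else truth.between_range
            )
            base = rng.uniform(lo, hi)
            d_ij = rng.uniform(-asymmetry_jitter, asymmetry_jitter)
            d_ji = rng.uniform(-asymmetry_jitter, asymmetry_jitter)
            values[i, j] = np.clip(base + d_ij, 0.0, 100.0)
            values[j, i] = np.clip(base + d_ji, 0.0, 100.0)
    return (
        LabeledMatrix(labels, values, kind="identity", scale="percent"),
        truth,
    )
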