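"""Configuration dataclasses shared across the pipeline.

Geometry mirrors the standard two-chamber laboratory setup for *Camponotus*
colonies: a dark nest box connected through a short tube to a foraging arena
under a light cycle.  All coordinates are millimetres, angles radians, frames
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open toward increasing coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("degenerate rectangle")

    def contains(self, x, y):
        """Vectorised half-open point-in-rectangle test."""
        return (
            (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)
        )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class ArenaGeometry:
    """Nest box, connecting tube and foraging arena.

    Defaults follow a 170 x 123 mm nest box and arena joined by a 19 mm-wide
    tube, laid out left (nest) to right (arena) in a shared coordinate frame.
    """

    nest: Rect = field(default_factory=lambda: Rect(0.0, 0.0, 170.0, 123.0))
    tube: Rect = field(default_factory=lambda: Rect(170.0, 52.0, 190.0, 71.0))
    arena: Rect = field(default_factory=lambda: Rect(190.0, 0.0, 360.0, 123.0))

    def classify(self, x, y):
        """Zone labels for points: 'nest', 'tube' or 'arena'.

        Points in none of the rectangles (numerical drift at the outer
        boundary) are attributed to the nearest chamber by x-coordinate.
        """
        import numpy as np

        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        zone = np.full(x.shape, "arena", dtype=object)
        zone[self.tube.contains(x, y)] = "tube"
        zone[self.nest.contains(x, y)] = "nest"
        # catch-all: anything left of the tube midpoint counts as nest side
        midpoint = 0.5 * (self.tube.x_min + self.tube.x_max)
        inside = (
            self.nest.contains(x, y) | self.tube.contains(x, y) | self.arena.contains(x, y)
        )
        zone[~inside & (x < midpoint)] = "nest"
        return zone


@dataclass(frozen=True)
class BodyGeometry:
    """Disk model of an ant's head and body regions derived from tag pose.

    The head disk centre sits ``head_offset`` mm ahead of the tag centre along
    the body axis; the body disk is centred on the tag.  Defaults are scaled
    from a mean body length of 8 mm (head_offset = 0.4 L, head_radius = 0.2 L,
    body_radius = 0.35 L).
    """

    mean_body_length: float = 8.0
    head_offset: float = 3.2
    head_radius: float = 1.6
    body_radius: float = 2.8

    def __post_init__(self) -> None:
        for name in ("mean_body_length", "head_offset", "head_radius", "body_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.head_radius >= self.mean_body_length:
            raise ValueError("head_radius must be smaller than mean_body_length")

    @classmethod
    def from_body_length(cls, length: float) -> "BodyGeometry":
        return cls(
            mean_body_length=length,
            head_offset=0.4 * length,
            head_radius=0.2 * length,
            body_radius=0.35 * length,
        )


@dataclass
class ColonyConfig:
    """Parameters of the synthetic colony generator.

    The defaults emulate the study design the analysis assumes: 4 queenright
    colonies of ~100 known-age workers, a U-shaped latent social maturity,
    maturity-correlated age and foraging, negative-binomial brain expression
    counts with maturity-driven effects plus extraction-batch effects, and an
    endosymbiont-dominated gut microbiota.
    """

    n_colonies: int = 4
    n_workers_per_colony: int = 100
    n_frames: int = 900
    frame_rate: float = 2.0
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    body: BodyGeometry = field(default_factory=BodyGeometry)

    # latent maturity and demography
    maturity_alpha: float = 0.5
    maturity_beta: float = 0.5
    age_maturity_correlation: float = 0.7

    # behaviour annotation
    n_sampled_frames: int = 80

    # tracking noise
    miss_rate: float = 0.05
    bad_tag_fraction: float = 0.04

    # brain gene expression
    n_genes: int = 1200
    n_de_genes: int = 120
    de_effect_size: float = 1.0          # log2 fold change per unit maturity
    dispersion: float = 0.3              # NB overdispersion
    n_batches: int = 4
    batch_effect_sd: float = 1.0         # log2-scale sd of gene x batch effects
    mean_expression: float = 30.0        # median per-gene per-worker base mean

    # gut microbiota
    n_asvs: int = 40
    endosymbiont_fraction: float = 0.9
    n_maturity_asvs: int = 5
    microbiota_depth: int = 20000
    dirichlet_concentration: float = 50.0

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_colonies": self.n_colonies,
            "n_workers_per_colony": self.n_workers_per_colony,
            "n_frames": self.n_frames,
            "n_genes": self.n_genes,
            "n_batches": self.n_batches,
            "n_asvs": self.n_asvs,
            "n_sampled_frames": self.n_sampled_frames,
            "microbiota_depth": self.microbiota_depth,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        if self.n_maturity_asvs < 0 or self.n_maturity_asvs >= self.n_asvs:
            raise ValueError("n_maturity_asvs must lie in [0, n_asvs)")
        if self.maturity_alpha <= 0 or self.maturity_beta <= 0:
            raise ValueError("Beta law parameters must be positive")
        for name in ("miss_rate", "bad_tag_fraction", "endosymbiont_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.age_maturity_correlation <= 1.0:
            raise ValueError("age_maturity_correlation must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
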