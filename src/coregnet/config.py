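"""Run configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: The six bioleaching-related pathway categories of *A. thiooxidans*
#: (RISC = reduced inorganic sulfur compounds, its electron donors).
DEFAULT_CATEGORIES = (
    "NAD biosynthesis",
    "Heme biosynthesis",
    "Spermidine biosynthesis",
    "Sulfur assimilation",
    "Energy generation",
    "RISC oxidation",
)

#: Uniform nucleotide background.
UNIFORM_BACKGROUND = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline.

    scan_p_threshold
        Per-occurrence p-value cut-off for motif matches when scanning
        promoters (default 1e-4). Matches at or below
        ``confident_p_threshold`` (default 1e-5) are additionally flagged
        as the confident class.
    final_arc_p_threshold
        Arcs selected by V-shapes whose original match p-value exceeds
        this bound (default 9e-5) are removed from the co-regulatory
        network.
    operon_max_gap
        Two consecutive same-strand genes belong to one operon iff the
        number of bases strictly between them is < this value (default
        50 bp); intergenic regions strictly longer than it are putative
        promoters.
    weight_classes
        Arc weights per p-value quantile group, ascending (default
        1, 2, 4, 8: lowest p-values get weight 1).
    """

    scan_p_threshold: float = 1e-4
    confident_p_threshold: float = 1e-5
    final_arc_p_threshold: float = 9e-5
    operon_max_gap: int = 50
    weight_classes: tuple[int, ...] = (1, 2, 4, 8)
    category_names: tuple[str, ...] = DEFAULT_CATEGORIES
    rng_seed: int = 0
    background_model: dict[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BACKGROUND)
    )

    def __post_init__(self) -> None:
        self.weight_classes = tuple(int(w) for w in self.weight_classes)
        self.category_names = tuple(self.category_names)
        for name in ("scan_p_threshold", "confident_p_threshold", "final_arc_p_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.operon_max_gap < 1:
            raise ValueError("operon_max_gap must be a positive bp count")
        ws = self.weight_classes
        if not ws or any(w <= 0 for w in ws) or any(a >= b for a, b in zip(ws, ws[1:])):
            raise ValueError("weight_classes must be strictly increasing positive integers")
        total = sum(self.background_model.get(b, 0.0) for b in "ACGT")
        if set(self.background_model) != set("ACGT") or abs(total - 1.0) > 1e-9:
            raise ValueError("background_model must assign ACGT probabilities summing to 1")

    # -- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["weight_classes"] = list(self.weight_classes)
        data["category_names"] = list(self.category_names)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
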