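"""Simulation configuration and the default vertebrate-style species ladder.

The default ladder mirrors the taxon chain used for duplication timing in
vertebrate gene-family studies (Eukaryota through Catarrhini down to
Homo sapiens), with one extant species branching off at every rank so that
presence/absence patterns can time a duplication to any rank.  The two-round
WGD sits by default on the branch entering Vertebrata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .errors import ConfigurationError
from .trees import SpeciesTree, TreeNode

#: (taxon, extant side-branch species) pairs, root-first.  The species listed
#: for the final taxon continues the chain as the focal extant lineage.
DEFAULT_LADDER: list[tuple[str, str]] = [
    ("Eukaryota", "Saccharomyces_cerevisiae"),
    ("Metazoa", "Nematostella_vectensis"),
    ("Bilateria", "Drosophila_melanogaster"),
    ("Chordata", "Ciona_intestinalis"),
    ("Vertebrata", "Danio_rerio"),
    ("Tetrapoda", "Xenopus_tropicalis"),
    ("Amniota", "Gallus_gallus"),
    ("Mammalia", "Monodelphis_domestica"),
    ("Eutheria", "Mus_musculus"),
    ("Catarrhini", "Macaca_mulatta"),
]

#: Extant species terminating the ladder (the focal species of the analyses).
DEFAULT_FOCAL_SPECIES = "Homo_sapiens"

#: Outgroup used for ancestral-ortholog (triad) analysis.
DEFAULT_OUTGROUP_SPECIES = "Drosophila_melanogaster"


def ladder_species_tree(
    ladder: Sequence[tuple[str, str]] | None = None,
    focal_species: str = DEFAULT_FOCAL_SPECIES,
) -> SpeciesTree:
    """Build the caterpillar species tree implied by a taxon ladder.

    Each taxon node has two children: the extant species that diverged at that
    rank, and the next (younger) taxon; the youngest taxon's second child is
    the focal species leaf.
    """
    ladder = list(ladder or DEFAULT_LADDER)
    if not ladder:
        raise ConfigurationError("empty species ladder")
    seen: set[str] = set()
    for taxon, species in ladder:
        if taxon in seen or species in seen:
            raise ConfigurationError(f"non-nested/duplicated ladder entry: {taxon}/{species}")
        seen.update((taxon, species))
    if focal_species in seen:
        raise ConfigurationError("focal species collides with a ladder entry")

    root = TreeNode(ladder[0][0])
    node = root
    for i, (taxon, species) in enumerate(ladder):
        node.name = taxon
        node.add_child(TreeNode(species))
        if i + 1 < len(ladder):
            node = node.add_child(TreeNode(ladder[i + 1][0]))
        else:
            node.add_child(TreeNode(focal_species))
    return SpeciesTree(root)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator.

    Probabilities live in [0, 1]; counts are positive.  Defaults encode the
    study conditions the downstream analyses assume: a ten-rank animal ladder,
    a two-round WGD on the Vertebrata stem with per-round retention of 0.15,
    a 47-tissue expression atlas, and a signed signalling network with mean
    ancestral degree ~6.2 whose polarity mix (positive/negative/scaffold)
    follows a curated human signalling map.
    """

    species_ladder: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_LADDER))
    focal_species: str = DEFAULT_FOCAL_SPECIES
    n_families: int = 200
    per_branch_dup_rate: float = 0.02
    loss_rate: float = 0.0
    wgd_branch: str = "Vertebrata"
    retention_round1: float = 0.15
    retention_round2: float = 0.15
    tandem_fraction: float = 0.7
    n_chromosomes: int = 8
    genes_per_chromosome: int = 250
    n_tissues: int = 47
    expression_base: tuple[float, float] = (5.3, 1.0)  # (location, scale) of ln-signal
    divergence_rate: float = 0.25  # per sqrt(ladder-step) sd of ln-signal drift
    wgd_tissue_boost: float = 1.0  # multiplicative brain boost for WGD descendants
    edge_inheritance_q: float = 0.7
    edge_gain_rate: float = 0.5
    bridging_prob: float = 0.107
    ancestral_mean_degree: float = 6.2
    polarity_freqs: tuple[float, float, float] = (0.475, 0.146, 0.379)
    seed: int = 17

    def validate(self) -> "SimulationConfig":
        probs = {
            "per_branch_dup_rate": self.per_branch_dup_rate,
            "loss_rate": self.loss_rate,
            "retention_round1": self.retention_round1,
            "retention_round2": self.retention_round2,
            "tandem_fraction": self.tandem_fraction,
            "edge_inheritance_q": self.edge_inheritance_q,
            "bridging_prob": self.bridging_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_families": self.n_families,
            "n_chromosomes": self.n_chromosomes,
            "genes_per_chromosome": self.genes_per_chromosome,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.n_tissues < 2:
            raise ConfigurationError("n_tissues must be at least 2")
        if self.edge_gain_rate < 0 or self.ancestral_mean_degree < 0:
            raise ConfigurationError("rates must be non-negative")
        if abs(sum(self.polarity_freqs) - 1.0) > 1e-9 or min(self.polarity_freqs) < 0:
            raise ConfigurationError("polarity_freqs must be a probability vector")
        taxa = [t for t, _ in self.species_ladder]
        if self.wgd_branch not in taxa:
            raise ConfigurationError(
                f"wgd_branch {self.wgd_branch!r} not a taxon of the species ladder")
        ladder_species_tree(self.species_ladder, self.focal_species)  # nesting check
        return self

    def species_tree(self) -> SpeciesTree:
        return ladder_species_tree(self.species_ladder, self.focal_species)

    def tissue_names(self) -> list[str]:
        # brain first so preferential-brain analyses have a canonical column
        return ["brain"] + [f"tissue_{i:02d}" for i in range(2, self.n_tissues + 1)]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        cfg = cls(**{k: v for k, v in data.items()})
        if isinstance(cfg.species_ladder, list):
            cfg.species_ladder = [tuple(e) for e in cfg.species_ladder]
        if isinstance(cfg.expression_base, list):
            cfg.expression_base = tuple(cfg.expression_base)
        if isinstance(cfg.polarity_freqs, list):
            cfg.polarity_freqs = tuple(cfg.polarity_freqs)
        return cfg.validate()

    @classmethod
    def from_json_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
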