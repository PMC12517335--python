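"""Synthetic datasets with the statistical structure the pipeline assumes.

Real protein language-model embeddings place orthologous proteins near each
other, so a dataset is emulated as a mixture of isotropic Gaussian blobs:
one blob per orthologous group, with the blob center drawn once per group
(spread ``center_scale``) and every member protein drawn around it with
within-group spread ``sigma``. Species membership of each group follows a
per-species copy-number distribution (default: 0 copies with probability
0.1, 1 with 0.8, 2 with 0.1 — mostly single-copy groups with occasional
losses and duplications); a group that draws zero copies everywhere is
redrawn so every group is populated. Dummy amino-acid sequences are uniform
random and carry no relation to the embeddings (the embedder itself is out
of scope here).

Generation is fully determined by the seed: the same config yields
byte-identical FASTA, group-map and embedding files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    EmbeddingMatrix,
    ProteinRecord,
    ProteinRegistry,
    write_embedding_table,
    write_fasta,
    write_group_map,
)
from .errors import EmptyInputError, ParameterError

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Default per-species copy-number distribution for a group.
DEFAULT_SIZE_MODEL = {0: 0.1, 1: 0.8, 2: 0.1}


@dataclass
class SynthConfig:
    """Parameters of the synthetic generator.

    ``size_model`` maps copy number -> probability for each (group, species)
    cell. ``center_scale`` is the standard deviation of blob centers;
    ``sigma`` the within-blob standard deviation, both in embedding units.
    """

    seed: int = 0
    n_species: int = 2
    n_groups: int = 100
    dim: int = 32
    size_model: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_MODEL))
    center_scale: float = 1.0
    sigma: float = 0.1
    seq_len_range: tuple[int, int] | None = (50, 200)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ParameterError(f"need >= 2 species, got {self.n_species}")
        if self.n_groups < 1:
            raise ParameterError(f"need >= 1 group, got {self.n_groups}")
        if self.dim < 1:
            raise ParameterError(f"need >= 1 dimension, got {self.dim}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.center_scale <= 0:
            raise ParameterError(f"center_scale must be > 0, got {self.center_scale}")
        if not self.size_model or any(p < 0 for p in self.size_model.values()):
            raise ParameterError("size_model must be a copy->probability mapping")
        total = sum(self.size_model.values())
        if not np.isclose(total, 1.0):
            raise ParameterError(f"size_model probabilities sum to {total}, not 1")
        if all(c == 0 for c, p in self.size_model.items() if p > 0):
            raise EmptyInputError("size_model puts all mass on 0 copies")


def species_codes(n_species: int) -> list[str]:
    """Short 4-letter species codes: spaa, spab, ..."""
    codes = []
    for i in range(n_species):
        codes.append("sp" + chr(ord("a") + i // 26) + chr(ord("a") + i % 26))
    return codes


def generate_dataset(config: SynthConfig) -> tuple[ProteinRegistry, EmbeddingMatrix]:
    """Draw a species-labeled, group-labeled dataset of Gaussian blobs.

    Returns the registry (with reference groups set) and the row-aligned
    embedding matrix. The emitted group labels are exactly the partition
    used to draw the embeddings.
    """
    rng = np.random.default_rng(config.seed)
    species = species_codes(config.n_species)
    copies = np.array(sorted(config.size_model), dtype=int)
    probs = np.array([config.size_model[c] for c in copies], dtype=float)
    probs = probs / probs.sum()

    records: list[ProteinRecord] = []
    rows: list[np.ndarray] = []
    counter = 0
    for g in range(config.n_groups):
        center = rng.normal(0.0, config.center_scale, size=config.dim)
        while True:
            counts = rng.choice(copies, size=config.n_species, p=probs)
            if counts.sum() > 0:
                break
        group_label = f"OG{g:05d}"
        for s, n_copies in zip(species, counts):
            for _ in range(int(n_copies)):
                emb = center
                if config.sigma > 0:
                    emb = center + rng.normal(0.0, config.sigma, size=config.dim)
                seq = None
                if config.seq_len_range is not None:
                    lo, hi = config.seq_len_range
                    length = int(rng.integers(lo, hi + 1))
                    seq = "".join(
                        _AA20[i] for i in rng.integers(0, len(_AA20), size=length)
                    )
                records.append(
                    ProteinRecord(
                        id=f"P{counter:06d}",
                        species=s,
                        sequence=seq,
                        group=group_label,
                        description="synthetic",
                    )
                )
                rows.append(np.asarray(emb, dtype=float))
                counter += 1
    if not records:
        raise EmptyInputError("config generated an empty dataset")
    registry = ProteinRegistry(records)
    matrix = EmbeddingMatrix(registry.ids, np.vstack(rows))
    return registry, matrix


def write_dataset(
    registry: ProteinRegistry, matrix: EmbeddingMatrix, outdir: str | Path
) -> dict[str, str]:
    """Write FASTA + group map TSV + embedding TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(outdir / "proteins.fasta"),
        "group_map": str(outdir / "groups.tsv"),
        "embeddings": str(outdir / "embeddings.tsv"),
    }
    write_fasta(registry, paths["fasta"])
    write_group_map(registry, paths["group_map"])
    write_embedding_table(matrix, paths["embeddings"])
    return paths
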