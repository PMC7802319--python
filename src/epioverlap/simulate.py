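"""Synthetic epimutation catalogs with planted colocalization structure.

Real catalogs come from upstream differential analyses of multi-generation
sperm samples (methylation arrays of DMRs, ncRNA expression, histone
retention); this module emulates their *processed* structure so that every
pipeline stage is testable without the deposited raw data:

* 2 exposure lineages x 3 generations (F1/F2/F3) x 3 marks;
* kilobase-scale features, each with a raw p-value drawn from one of
  three explicit tiers — planted-stringent (passes the per-mark stringent
  cutoff), near-miss (passes only the relaxed p < 0.05), and background
  (passes neither);
* latent genomic loci shared across generations that plant cross-mark
  colocalization (tri-mark loci carry DHR + ncRNA at F3) and
  cross-generation DMR retention (a configurable fraction of F1 DMR loci
  re-emitted in F2 and F3);
* DHRs present only in the generations configured (F3 by default — the
  transgenerational generation is where differential histone retention
  appears);
* positional jitter around each latent locus, so that direct overlap is
  partial while a 10 kb window recovers the planted colocalization.

Everything is deterministic under the configured seed, and a ground-truth
record of every latent locus enables exact recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import Epimutation, EpimutationSet, write_catalog
from .genome import GenomeAssembly, GenomicInterval, write_assembly

TRI = ("DMR", "DHR", "ncRNA")


@dataclass
class SyntheticConfig:
    """All knobs of the catalog generator.

    Defaults encode the structure the analysis assumes: 35% of F1 DMR
    loci retained through F2 and F3, 25% of latent loci carrying the
    tri-mark (DMR+DHR+ncRNA) signature at F3, 30% carrying an F1
    ncRNA-DMR pair, and DHRs present only in F3. The genome is a
    desk-scale stand-in (20 x 10 Mb chromosomes).
    """

    seed: int = 0
    n_chrom: int = 20
    chrom_length_bp: Union[int, Sequence[int]] = 10_000_000
    n_latent_loci: int = 600
    mark_widths: Mapping[str, int] = field(
        default_factory=lambda: {"DMR": 1000, "DHR": 1000, "ncRNA": 500}
    )
    #: fraction of latent loci planting all three marks (DHR+ncRNA added in
    #: the DHR generations) or an F1 ncRNA alongside the locus DMR
    tri_colocalization: float = 0.25
    pair_ncrna_colocalization: float = 0.30
    dmr_retention: float = 0.35
    dhr_generations: tuple[str, ...] = ("F3",)
    #: independently planted (non-colocalized) stringent loci per set
    n_solo: Mapping[str, int] = field(
        default_factory=lambda: {"DMR": 0, "ncRNA": 150, "DHR": 100}
    )
    jitter_bp: int = 2000
    #: p-value tiers: planted features draw 10**-U(a, b) per mark;
    #: near-miss U(1e-4, 0.05); background U(0.05, 1)
    stringent_exponents: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "DMR": (6.0, 12.0),
            "DHR": (6.0, 12.0),
            "ncRNA": (4.0, 10.0),
        }
    )
    near_miss_range: tuple[float, float] = (1e-4, 0.05)
    background_range: tuple[float, float] = (0.05, 1.0)
    n_near_miss: int = 200
    n_background: int = 300
    lineages: tuple[str, ...] = ("vinclozolin", "DDT")
    ncrna_subtypes: tuple[str, ...] = ("sncRNA", "lncRNA")

    def __post_init__(self) -> None:
        for name, frac in (
            ("tri_colocalization", self.tri_colocalization),
            ("pair_ncrna_colocalization", self.pair_ncrna_colocalization),
            ("dmr_retention", self.dmr_retention),
        ):
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if any(w < 1 for w in self.mark_widths.values()):
            raise ValueError("mark widths must be >= 1 bp")
        if self.jitter_bp < 0:
            raise ValueError("jitter_bp must be >= 0")

    def chrom_lengths(self) -> list[int]:
        if isinstance(self.chrom_length_bp, int):
            return [self.chrom_length_bp] * self.n_chrom
        lengths = list(self.chrom_length_bp)
        if len(lengths) != self.n_chrom:
            raise ValueError(
                f"chrom_length_bp has {len(lengths)} entries for "
                f"n_chrom={self.n_chrom}"
            )
        return lengths

    def to_json(self) -> str:
        d = asdict(self)
        d["mark_widths"] = dict(self.mark_widths)
        d["n_solo"] = dict(self.n_solo)
        d["stringent_exponents"] = {
            k: list(v) for k, v in self.stringent_exponents.items()
        }
        return json.dumps(d, indent=2, default=list)


@dataclass
class PlantedLocus:
    """Ground-truth record of one latent locus."""

    locus_id: str
    lineage: str
    chrom: str
    center: int
    dmr_retained: bool
    tri_mark: bool
    f1_ncrna_pair: bool
    feature_ids: list[str] = field(default_factory=list)


def build_assembly(cfg: SyntheticConfig) -> GenomeAssembly:
    return GenomeAssembly(
        (f"chr{i + 1}", length)
        for i, length in enumerate(cfg.chrom_lengths())
    )


def _uniform_positions(
    n: int, assembly: GenomeAssembly, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """n genomic positions, uniform over total genome length."""
    lengths = np.array([l for _, l in assembly.chromosomes], dtype=float)
    idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    offsets = rng.integers(0, lengths.astype(np.int64)[idx])
    names = assembly.names
    return [(names[i], int(o)) for i, o in zip(idx, offsets)]


def generate_catalog(
    cfg: SyntheticConfig,
) -> tuple[GenomeAssembly, list[EpimutationSet], list[PlantedLocus]]:
    """Generate a full synthetic catalog plus its ground truth.

    Deterministic under ``cfg.seed``. Each lineage has independent latent
    loci (independent genomic sites are induced by each exposure). Per
    lineage:

    * every latent locus plants an F1 stringent DMR; with probability
      ``dmr_retention`` the locus is *retained* and re-emits a stringent
      DMR in F2 and F3 (fresh jitter and p-value per generation);
    * with probability ``tri_colocalization`` a locus additionally plants
      a stringent DHR and ncRNA in each DHR generation (F3 by default) —
      independent of retention, so the tri-mark fraction among F3 DMRs
      equals the configured fraction in expectation;
    * with probability ``pair_ncrna_colocalization`` a locus plants a
      stringent F1 ncRNA;
    * ``n_solo[mark]`` extra stringent loci per active generation, and
      ``n_near_miss`` / ``n_background`` weaker features per set, are
      placed at fresh uniform positions.

    Raises if the planted features cannot plausibly fit the genome.
    """
    assembly = build_assembly(cfg)
    widths = dict(cfg.mark_widths)
    max_width = max(widths.values())
    demand = (cfg.n_latent_loci * 3 + sum(cfg.n_solo.values()) * 3) * (
        max_width + 2 * cfg.jitter_bp
    )
    if demand > assembly.total_bp:
        raise ValueError(
            f"infeasible placement: ~{demand:,} bp of planted features on a "
            f"{assembly.total_bp:,} bp genome"
        )

    rng = np.random.default_rng(cfg.seed)
    ground_truth: list[PlantedLocus] = []
    # members keyed by (lineage, generation, mark)
    members: dict[tuple[str, str, str], list[Epimutation]] = {
        (lineage, gen, mark): []
        for lineage in cfg.lineages
        for gen in ("F1", "F2", "F3")
        for mark in ("DMR", "ncRNA", "DHR")
    }
    counters: dict[tuple[str, str, str], int] = {}

    def stringent_p(mark: str) -> float:
        lo, hi = cfg.stringent_exponents[mark]
        return float(10.0 ** -rng.uniform(lo, hi))

    def emit(
        lineage: str,
        gen: str,
        mark: str,
        chrom: str,
        center: int,
        p: float,
        jitter: bool = True,
        subtype: Optional[str] = None,
    ) -> str:
        key = (lineage, gen, mark)
        counters[key] = counters.get(key, 0) + 1
        if jitter and cfg.jitter_bp > 0:
            center = center + int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
        w = widths[mark]
        # keep the feature fully on-chromosome (clamp, don't truncate)
        start = max(0, min(center - w // 2, assembly.length_of(chrom) - w))
        iv = GenomicInterval(chrom, start, start + w)
        if mark == "ncRNA" and subtype is None:
            subtype = cfg.ncrna_subtypes[
                int(rng.integers(0, len(cfg.ncrna_subtypes)))
            ]
        eid = f"{lineage}_{gen}_{mark}_{counters[key]:05d}"
        members[key].append(
            Epimutation(
                id=eid,
                interval=iv,
                mark=mark,
                generation=gen,
                lineage=lineage,
                p_value=p,
                subtype=subtype,
            )
        )
        return eid

    for lineage in cfg.lineages:
        positions = _uniform_positions(cfg.n_latent_loci, assembly, rng)
        retained = rng.random(cfg.n_latent_loci) < cfg.dmr_retention
        tri = rng.random(cfg.n_latent_loci) < cfg.tri_colocalization
        pair = rng.random(cfg.n_latent_loci) < cfg.pair_ncrna_colocalization
        for k, (chrom, center) in enumerate(positions):
            locus = PlantedLocus(
                locus_id=f"{lineage}_locus_{k:05d}",
                lineage=lineage,
                chrom=chrom,
                center=center,
                dmr_retained=bool(retained[k]),
                tri_mark=bool(tri[k]),
                f1_ncrna_pair=bool(pair[k]),
            )
            dmr_gens = ("F1", "F2", "F3") if retained[k] else ("F1",)
            for gen in dmr_gens:
                locus.feature_ids.append(
                    emit(lineage, gen, "DMR", chrom, center, stringent_p("DMR"))
                )
            if tri[k]:
                for gen in cfg.dhr_generations:
                    locus.feature_ids.append(
                        emit(lineage, gen, "DHR", chrom, center,
                             stringent_p("DHR"))
                    )
                    locus.feature_ids.append(
                        emit(lineage, gen, "ncRNA", chrom, center,
                             stringent_p("ncRNA"))
                    )
            if pair[k]:
                locus.feature_ids.append(
                    emit(lineage, "F1", "ncRNA", chrom, center,
                         stringent_p("ncRNA"))
                )
            ground_truth.append(locus)

        # independently planted stringent loci (not colocalized by design);
        # recorded in the ground truth with a "solo" locus id
        for mark, n_solo in cfg.n_solo.items():
            active = (
                cfg.dhr_generations if mark == "DHR" else ("F1", "F2", "F3")
            )
            for gen in active:
                for j, (chrom, center) in enumerate(
                    _uniform_positions(n_solo, assembly, rng)
                ):
                    fid = emit(lineage, gen, mark, chrom, center,
                               stringent_p(mark))
                    ground_truth.append(
                        PlantedLocus(
                            locus_id=f"{lineage}_solo_{mark}_{gen}_{j:05d}",
                            lineage=lineage,
                            chrom=chrom,
                            center=center,
                            dmr_retained=False,
                            tri_mark=False,
                            f1_ncrna_pair=False,
                            feature_ids=[fid],
                        )
                    )

        # near-miss and background tiers for every non-empty set
        for gen in ("F1", "F2", "F3"):
            for mark in ("DMR", "ncRNA", "DHR"):
                if mark == "DHR" and gen not in cfg.dhr_generations:
                    continue  # DHRs absent outside their generations
                for n, (lo, hi) in (
                    (cfg.n_near_miss, cfg.near_miss_range),
                    (cfg.n_background, cfg.background_range),
                ):
                    for chrom, center in _uniform_positions(n, assembly, rng):
                        emit(
                            lineage, gen, mark, chrom, center,
                            float(rng.uniform(lo, hi)), jitter=False,
                        )

    catalog = [
        EpimutationSet(lineage, gen, mark, ms)
        for (lineage, gen, mark), ms in members.items()
    ]
    return assembly, catalog, ground_truth


def generate_gene_annotation(
    assembly: GenomeAssembly,
    n_genes: int,
    rng: np.random.Generator,
    gene_length_bp: int = 20_000,
) -> pd.DataFrame:
    """Non-overlapping gene intervals spread uniformly over the genome.

    Genes are laid out on an evenly spaced grid with random offsets, so
    they never overlap; symbols are ``GENE00001``-style. Returns a
    DataFrame with columns (chrom, start, end, symbol) sorted by
    position.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rows = []
    if n_genes > 0:
        lengths = np.array([l for _, l in assembly.chromosomes], dtype=float)
        per_chrom = np.floor(lengths / lengths.sum() * n_genes).astype(int)
        while per_chrom.sum() < n_genes:
            per_chrom[int(np.argmax(lengths / (per_chrom + 1)))] += 1
        gene_no = 0
        for (chrom, length), k in zip(assembly.chromosomes, per_chrom):
            if k == 0:
                continue
            slot = length // k
            if slot < gene_length_bp:
                raise ValueError(
                    f"infeasible gene density: {k} genes of "
                    f"{gene_length_bp} bp on {chrom} ({length} bp)"
                )
            for j in range(k):
                offset = int(rng.integers(0, slot - gene_length_bp + 1))
                start = j * slot + offset
                gene_no += 1
                rows.append(
                    (chrom, start, start + gene_length_bp, f"GENE{gene_no:05d}")
                )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


def write_ground_truth(
    ground_truth: Sequence[PlantedLocus], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(g) for g in ground_truth], fh, indent=1)


def write_simulation(
    cfg: SyntheticConfig, out_dir: Union[str, Path]
) -> Path:
    """Generate and serialize a full simulation (assembly, catalog tables,
    ground truth, config) into a directory; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assembly, catalog, ground_truth = generate_catalog(cfg)
    write_assembly(assembly, out_dir / "assembly.chrom.sizes")
    write_catalog(catalog, out_dir)
    write_ground_truth(ground_truth, out_dir / "ground_truth.json")
    (out_dir / "config.json").write_text(cfg.to_json())
    return out_dir
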