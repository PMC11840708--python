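"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, all pure functions of their configuration (seed included):

* primer-planted genomes — random ACGT background with forward/reverse primer
  sites planted at a controlled insert length, for a controlled fraction of
  amplifiable genomes;
* identity ladders — substitution-only mutants of a 16S-like reference at
  exact target percent identities, each carrying the novelty rank its
  realized identity implies;
* depth-stratified communities — a 15-sample, 4-layer survey design whose
  target-phylum (Planctomycetota) ASV pool grows below the deep chlorophyll
  maximum, with log-normal relative abundances and multinomial read counts.

The community generator encodes the layer effect as richness (pool size),
not as mean-abundance shifts, mirroring the observed-features framing of the
survey it emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    LAYERS,
    AsvTable,
    RankedTaxonomy,
    SequenceRecord,
    parse_taxonomy_string,
    write_asv_table,
)
from .insilico_pcr import IUPAC_SETS, PrimerPair, reverse_complement
from .taxonomy_rank import RankThresholds, delineate

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_random_reference(
    length: int = 1500, seed: int = 0, name: str = "ref"
) -> SequenceRecord:
    """A uniform-random 16S-length DNA reference sequence."""
    rng = np.random.default_rng(seed)
    return SequenceRecord(id=name, seq=_random_dna(rng, length))


# ---------------------------------------------------------------------------
# Primer-planted genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """Configuration of a primer-planted genome set.

    mismatch_mode controls how NON-amplifiable genomes are built:
    ``missing_site`` omits the reverse-primer site, ``broken_site`` corrupts
    three positions of it with incompatible bases, ``degenerate_compatible``
    corrupts the primer's degenerate positions specifically (falling back to
    arbitrary positions when fewer than three exist).
    """

    primer_pair: PrimerPair
    n_genomes: int = 130
    fraction_amplifiable: float = 0.6
    mismatch_mode: str = "missing_site"
    insert_length: int = 0  # 0 = midpoint of the pair's window
    flank_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_amplifiable <= 1.0:
            raise ValueError("fraction_amplifiable must be in [0, 1]")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be positive")
        if self.mismatch_mode not in (
            "degenerate_compatible", "broken_site", "missing_site"
        ):
            raise ValueError(f"unknown mismatch_mode {self.mismatch_mode!r}")
        if self.insert_length == 0:
            mid = (self.primer_pair.min_len + self.primer_pair.max_len) // 2
            object.__setattr__(self, "insert_length", mid)
        if not (self.primer_pair.min_len
                <= self.insert_length <= self.primer_pair.max_len):
            raise ValueError(
                f"insert_length {self.insert_length} outside the pair window "
                f"[{self.primer_pair.min_len}, {self.primer_pair.max_len}]"
            )


def _realize_primer(rng: np.random.Generator, primer: str) -> str:
    """Fill each degenerate position with a uniformly chosen compatible base."""
    out = []
    for ch in primer:
        opts = sorted(IUPAC_SETS[ch])
        out.append(opts[rng.integers(0, len(opts))])
    return "".join(out)


def _corrupt(rng: np.random.Generator, site: str, primer: str,
              positions: Sequence[int]) -> str:
    """Replace the given site positions with bases incompatible with the primer."""
    chars = list(site)
    for pos in positions:
        incompatible = sorted(set("ACGT") - IUPAC_SETS[primer[pos]])
        chars[pos] = incompatible[rng.integers(0, len(incompatible))]
    return "".join(chars)


def make_planted_genomes(
    spec: PlantSpec,
) -> tuple[list[SequenceRecord], dict[str, bool]]:
    """Generate genomes with planted primer sites and their ground truth.

    Exactly round(n_genomes * fraction_amplifiable) genomes carry a
    forward-compatible site and, ``insert_length`` downstream, the reverse
    complement of a reverse-compatible site; the rest are non-amplifiable per
    ``mismatch_mode``. Background sequence is i.i.d. uniform ACGT.
    """
    rng = np.random.default_rng(spec.seed)
    pair = spec.primer_pair
    fwd_len, rev_len = len(pair.forward), len(pair.reverse)
    core_len = spec.insert_length - fwd_len - rev_len
    if core_len < 0:
        raise ValueError("insert_length shorter than the two primers combined")

    n_amp = round(spec.n_genomes * spec.fraction_amplifiable)
    truth: dict[str, bool] = {}
    genomes: list[SequenceRecord] = []
    for k in range(spec.n_genomes):
        gid = f"genome_{k:04d}"
        amplifiable = k < n_amp
        fwd_site = _realize_primer(rng, pair.forward)
        rev_site = _realize_primer(rng, pair.reverse)
        left = _random_dna(rng, spec.flank_length)
        core = _random_dna(rng, core_len)
        right = _random_dna(rng, spec.flank_length)
        if amplifiable:
            seq = left + fwd_site + core + reverse_complement(rev_site) + right
        elif spec.mismatch_mode == "missing_site":
            seq = left + fwd_site + core + _random_dna(rng, rev_len) + right
        else:
            if spec.mismatch_mode == "degenerate_compatible":
                degenerate = [i for i, c in enumerate(pair.reverse) if c not in "ACGT"]
                positions = degenerate[:3] if len(degenerate) >= 3 else None
            else:
                positions = None
            if positions is None:
                positions = sorted(rng.choice(rev_len, size=3, replace=False))
            broken = _corrupt(rng, rev_site, pair.reverse, positions)
            seq = left + fwd_site + core + reverse_complement(broken) + right
        truth[gid] = amplifiable
        genomes.append(SequenceRecord(id=gid, seq=seq))
    return genomes, truth


# ---------------------------------------------------------------------------
# Identity ladders
# ---------------------------------------------------------------------------

def make_identity_ladder(
    reference: SequenceRecord,
    target_identities: Sequence[float],
    seed: int = 0,
    thresholds: RankThresholds = RankThresholds(),
) -> list[tuple[SequenceRecord, float, str]]:
    """Substitution-only mutants of a reference at target percent identities.

    Each query substitutes exactly round(L * (1 - t/100)) positions (no
    indels), so the realized ungapped identity is exact; the planted novelty
    rank is the Yarza-threshold call implied by the realized identity.
    """
    if len(reference.seq) < 800:
        raise ValueError("reference must be >= 800 bases (16S-like)")
    rng = np.random.default_rng(seed)
    L = len(reference.seq)
    out: list[tuple[SequenceRecord, float, str]] = []
    for i, target in enumerate(target_identities):
        if not 0.0 < target <= 100.0:
            raise ValueError(f"target identity {target} outside (0, 100]")
        k = round(L * (1.0 - target / 100.0))
        chars = list(reference.seq)
        for pos in rng.choice(L, size=k, replace=False):
            alternatives = sorted(set("ACGT") - {chars[pos]})
            chars[pos] = alternatives[rng.integers(0, 3)]
        realized = 100.0 * (L - k) / L
        _, novelty = delineate(realized, thresholds)
        query = SequenceRecord(
            id=f"query_{i:03d}_t{target:g}", seq="".join(chars),
            description=f"target={target:g} realized={realized:.4f}",
        )
        out.append((query, realized, novelty))
    return out


# ---------------------------------------------------------------------------
# Depth-stratified communities
# ---------------------------------------------------------------------------

#: Planctomycetota class -> (order, family) used for generated target ASVs;
#: OM190 is a deep-branching lineage without described ranks below class.
_TARGET_LINEAGES = (
    ("Planctomycetia", "Pirellulales", "Pirellulaceae"),
    ("Phycisphaerae", "Phycisphaerales", "Phycisphaeraceae"),
    ("Candidatus Brocadiia", "CA Brocadiales", "CA Brocadiaceae"),
    ("OM190", "", ""),
)

_BACKGROUND_PHYLA = (
    "Proteobacteria", "Bacteroidota", "Cyanobacteria", "Actinobacteriota",
    "Verrucomicrobiota", "Chloroflexi", "Marinisomatota", "Acidobacteriota",
)


@dataclass(frozen=True)
class CommunityConfig:
    """Study-design parameters of the synthetic amplicon survey.

    Defaults mirror the emulated cruise: 15 samples over four depth layers
    (4 surface, 4 DCM, 3 below-DCM, 4 mesopelagic) with target-phylum ASV
    pools that grow with depth; reads_per_sample is of the order of the
    survey's long-read per-sample depth.
    """

    samples_per_layer: Mapping[str, int] = field(
        default_factory=lambda: {
            "surface": 4, "dcm": 4, "below_dcm": 3, "mesopelagic": 4
        }
    )
    pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "surface": 10, "dcm": 10, "below_dcm": 40, "mesopelagic": 40
        }
    )
    background_asvs: int = 200
    reads_per_sample: int = 20000
    abundance_dispersion: float = 1.0
    target_phylum: str = "Planctomycetota"
    seed: int = 0

    def __post_init__(self) -> None:
        for layer in LAYERS:
            if self.samples_per_layer.get(layer, 0) < 1:
                raise ValueError(f"samples_per_layer[{layer!r}] must be positive")
            if self.pool_sizes.get(layer, 0) < 1:
                raise ValueError(f"pool_sizes[{layer!r}] must be positive")
        sizes = [self.pool_sizes[l] for l in LAYERS]
        if any(b < a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("pool_sizes must be monotone non-decreasing with depth")
        if self.background_asvs < 1:
            raise ValueError("background_asvs must be positive")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be positive")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be positive")


def _target_taxonomy(i: int, phylum: str) -> RankedTaxonomy:
    cls, order, family = _TARGET_LINEAGES[i % len(_TARGET_LINEAGES)]
    return parse_taxonomy_string(";".join(["Bacteria", phylum, cls, order, family]))


def _background_taxonomy(i: int) -> RankedTaxonomy:
    phylum = _BACKGROUND_PHYLA[i % len(_BACKGROUND_PHYLA)]
    return parse_taxonomy_string(f"Bacteria;{phylum}")


def make_community(
    config: CommunityConfig = CommunityConfig(),
) -> tuple[AsvTable, dict[str, RankedTaxonomy], dict[str, int]]:
    """Generate the depth-stratified ASV table, its taxonomy and ground truth.

    Layer pools are nested prefixes of a global target-phylum ASV list, so
    deeper layers contain every shallow ASV plus extras. Per sample, relative
    abundances over (layer pool + shared background pool) are log-normal with
    sigma = abundance_dispersion; counts are multinomial at reads_per_sample.
    Ground truth is the per-layer target-phylum pool size.
    """
    rng = np.random.default_rng(config.seed)
    max_pool = max(config.pool_sizes[l] for l in LAYERS)
    target_ids = [f"pla_{i:04d}" for i in range(max_pool)]
    background_ids = [f"bg_{i:04d}" for i in range(config.background_asvs)]
    asv_ids = target_ids + background_ids

    taxonomy: dict[str, RankedTaxonomy] = {}
    for i, aid in enumerate(target_ids):
        taxonomy[aid] = _target_taxonomy(i, config.target_phylum)
    for i, aid in enumerate(background_ids):
        taxonomy[aid] = _background_taxonomy(i)

    sample_ids: list[str] = []
    layer_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    col_of = {aid: j for j, aid in enumerate(asv_ids)}
    for layer in LAYERS:
        pool = target_ids[: config.pool_sizes[layer]] + background_ids
        pool_cols = np.array([col_of[a] for a in pool])
        for k in range(config.samples_per_layer[layer]):
            sid = f"{layer}_{k + 1}"
            sample_ids.append(sid)
            layer_of[sid] = layer
            abundance = rng.lognormal(
                mean=0.0, sigma=config.abundance_dispersion, size=len(pool)
            )
            probs = abundance / abundance.sum()
            counts = rng.multinomial(config.reads_per_sample, probs)
            row = np.zeros(len(asv_ids), dtype=np.int64)
            row[pool_cols] = counts
            rows.append(row)

    table = AsvTable(
        sample_ids=sample_ids,
        asv_ids=asv_ids,
        counts=np.vstack(rows),
        layer_of=layer_of,
    )
    truth = {layer: int(config.pool_sizes[layer]) for layer in LAYERS}
    return table, taxonomy, truth


def write_community(
    outdir: str | Path,
    config: CommunityConfig = CommunityConfig(),
) -> dict[str, Path]:
    """Generate a community and write counts/taxonomy/metadata TSVs plus a
    ground-truth sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, taxonomy, truth = make_community(config)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_asv_table(table, taxonomy, paths["counts"], paths["taxonomy"],
                    paths["metadata"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        fh.write("layer\ttarget_pool_size\n")
        for layer in LAYERS:
            fh.write(f"{layer}\t{truth[layer]}\n")
    return paths
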