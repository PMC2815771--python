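"""Benchmark dataset assembly and on-disk representation.

A benchmark dataset is a set of promoter-like sequences with embedded
transcription-factor binding sites and a ground-truth record of where
every site is.  Three "information spaces" are generated:

* **coregulation** — ten independent promoters of one reference species,
  each with one site from a common motif;
* **orthologous** — one promoter together with its simulated orthologs,
  related through a phylogeny;
* **combined** — both: each coregulated promoter comes with its
  orthologous set.

Datasets are written as plain text: a FASTA of sequences, a GFF3 of
ground-truth sites (1-based inclusive coordinates, feature type
``TF_binding_site``) and a JSON manifest holding the generation config
and seed, from which the dataset can be regenerated bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolve import LossSpec, decode, encode, evolve_sequence, _draw_categorical
from .motif import WeightMatrix, _validate_probs, generate_wm, sample_site, uniform_background
from .phylo import PhyloTree, parse_newick, star_tree, write_newick

REFERENCE_SPECIES = "REF"


@dataclass(frozen=True)
class SequenceRecord:
    dataset_id: str
    species: str
    gene: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")


@dataclass(frozen=True)
class GroundTruthSite:
    """Embedded site location, 0-based half-open, + strand."""

    species: str
    gene: str
    start: int
    end: int
    strand: str = "+"
    wm_label: str = ""

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid site interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrthologousSet:
    """One reference gene's record plus its orthologs."""

    gene: str
    members: list[SequenceRecord]

    def __post_init__(self):
        n_ref = sum(1 for r in self.members if r.species == REFERENCE_SPECIES)
        if n_ref != 1:
            raise ValueError(f"orthologous set {self.gene} has {n_ref} reference records")


@dataclass
class BenchmarkDataset:
    dataset_id: str
    space: str  # coregulation | orthologous | combined
    records: list[SequenceRecord]
    sites: list[GroundTruthSite]
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.space not in ("coregulation", "orthologous", "combined"):
            raise ValueError(f"unknown space {self.space!r}")
        keys = [(r.species, r.gene) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("(species, gene) pairs must be unique within a dataset")
        lengths = {len(r.sequence) for r in self.records}
        by_key = {k: l for k, l in zip(keys, (len(r.sequence) for r in self.records))}
        for s in self.sites:
            if (s.species, s.gene) not in by_key:
                raise ValueError(f"ground-truth site references unknown record {(s.species, s.gene)}")
            if s.end > by_key[(s.species, s.gene)]:
                raise ValueError("ground-truth site extends beyond its sequence")
        sets = self.ortholog_sets()
        if self.space == "coregulation" and any(len(s.members) != 1 for s in sets):
            raise ValueError("coregulation space requires single-member sets")
        if self.space == "orthologous" and len(sets) != 1:
            raise ValueError("orthologous space requires exactly one orthologous set")
        if self.space == "combined" and (
            len(sets) < 2 or any(len(s.members) < 2 for s in sets)
        ):
            raise ValueError("combined space requires >=2 sets each with >=2 members")

    def ortholog_sets(self) -> list[OrthologousSet]:
        by_gene: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            by_gene.setdefault(r.gene, []).append(r)
        return [OrthologousSet(g, members) for g, members in sorted(by_gene.items())]

    def record(self, species: str, gene: str) -> SequenceRecord:
        for r in self.records:
            if r.species == species and r.gene == gene:
                return r
        raise KeyError((species, gene))


def gene_label(i: int) -> str:
    return f"g{i}"


def make_ancestor(
    bg_length: int,
    wm: WeightMatrix,
    rng: np.random.Generator,
    background: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """I.i.d. background of ``bg_length`` with one sampled site
    overwriting a uniformly chosen window.  Returns (sequence, start)."""
    if bg_length < wm.width:
        raise ValueError("background length shorter than motif width")
    if background is None:
        background = uniform_background()
    background = _validate_probs(background, "background")
    seq = _draw_categorical(background, bg_length, rng)
    start = int(rng.integers(0, bg_length - wm.width + 1))
    seq[start : start + wm.width] = encode(sample_site(wm, rng).sequence)
    return seq, start


def _background_ancestor(bg_length, rng, background):
    return _draw_categorical(background, bg_length, rng)


def simulate_coregulation_space(
    n_genes: int,
    wm: WeightMatrix,
    ref_proximity: float = 0.80,
    bg_length: int = 500,
    dropout_k: int = 0,
    rng: np.random.Generator | None = None,
    dataset_id: str = "coreg",
    background: np.ndarray | None = None,
) -> BenchmarkDataset:
    """Coregulation space: ``n_genes`` reference promoters, each evolved
    from an independent ancestor over a single branch of proximity
    ``ref_proximity``; ``dropout_k`` randomly chosen genes carry no
    site."""
    if not 0 <= dropout_k <= n_genes:
        raise ValueError("dropout_k must lie in [0, n_genes]")
    rng = rng if rng is not None else np.random.default_rng()
    bg = uniform_background() if background is None else _validate_probs(background, "background")
    dropped = set(rng.choice(n_genes, size=dropout_k, replace=False).tolist())
    tree = star_tree([ref_proximity], [REFERENCE_SPECIES])
    records, sites = [], []
    for i in range(n_genes):
        gene = gene_label(i)
        if i in dropped:
            anc, site = _background_ancestor(bg_length, rng, bg), None
        else:
            anc, start = make_ancestor(bg_length, wm, rng, bg)
            site = (start, wm)
        leaves = evolve_sequence(anc, tree, site=site, rng=rng, background=bg)
        leaf = leaves[REFERENCE_SPECIES]
        records.append(SequenceRecord(dataset_id, REFERENCE_SPECIES, gene, decode(leaf.sequence)))
        if leaf.site_start is not None:
            sites.append(
                GroundTruthSite(
                    REFERENCE_SPECIES, gene, leaf.site_start, leaf.site_start + wm.width,
                    wm_label=wm.label,
                )
            )
    return BenchmarkDataset(dataset_id, "coregulation", records, sites)


def simulate_combined_space(
    n_genes: int,
    wm: WeightMatrix,
    tree: PhyloTree,
    loss: LossSpec | None = None,
    bg_length: int = 500,
    rng: np.random.Generator | None = None,
    dataset_id: str = "combined",
    background: np.ndarray | None = None,
    space: str = "combined",
) -> BenchmarkDataset:
    """Combined coregulation-orthology space: one orthologous set per
    gene, each evolved from an independent ancestor down ``tree``.

    Loss in the coregulation direction (``loss.lost_genes``, gene
    indices) removes the site from the reference gene and all its
    orthologs: the whole ancestor is plain background.  Loss in the
    orthologous direction (``loss.lost_species``) replaces the site
    window at those leaves with background.
    """
    loss = loss or LossSpec()
    rng = rng if rng is not None else np.random.default_rng()
    bg = uniform_background() if background is None else _validate_probs(background, "background")
    if REFERENCE_SPECIES not in tree.leaf_labels():
        raise ValueError(f"tree must contain the reference leaf {REFERENCE_SPECIES!r}")
    bad_genes = {g for g in loss.lost_genes if not 0 <= g < n_genes}
    if bad_genes:
        raise ValueError(f"lost gene indices out of range: {sorted(bad_genes)}")
    records, sites = [], []
    for i in range(n_genes):
        gene = gene_label(i)
        if i in loss.lost_genes:
            anc, site = _background_ancestor(bg_length, rng, bg), None
        else:
            anc, start = make_ancestor(bg_length, wm, rng, bg)
            site = (start, wm)
        leaves = evolve_sequence(anc, tree, site=site, loss=loss, rng=rng, background=bg)
        for species in tree.leaf_labels():
            leaf = leaves[species]
            records.append(SequenceRecord(dataset_id, species, gene, decode(leaf.sequence)))
            if leaf.site_start is not None:
                sites.append(
                    GroundTruthSite(
                        species, gene, leaf.site_start, leaf.site_start + wm.width,
                        wm_label=wm.label,
                    )
                )
    return BenchmarkDataset(dataset_id, space, records, sites)


def simulate_orthologous_space(
    wm: WeightMatrix,
    tree: PhyloTree,
    bg_length: int = 500,
    rng: np.random.Generator | None = None,
    dataset_id: str = "ortho",
    loss: LossSpec | None = None,
    background: np.ndarray | None = None,
) -> BenchmarkDataset:
    """Orthologous space: a single reference promoter plus its
    simulated orthologs (the combined space with one gene)."""
    return simulate_combined_space(
        1, wm, tree, loss=loss, bg_length=bg_length, rng=rng,
        dataset_id=dataset_id, background=background, space="orthologous",
    )


# ---------------------------------------------------------------------------
# configuration-driven generation

DEFAULT_CONFIG = {
    "space": "coregulation",
    "width": 13,
    "target_ic": 24.0,
    "ic_tolerance": 0.25,
    "wm_label": "motif",
    "bg_length": 500,
    "n_genes": 10,
    "ref_proximity": 0.80,
    "dropout_k": 0,
    "tree": None,  # Newick string (combined / orthologous spaces)
    "branch_mode": "proximity",
    "lost_species": [],
    "lost_genes": [],
    "background": None,  # None -> uniform (Jukes-Cantor background)
}


def simulate_from_config(config: dict, seed: int, dataset_id: str | None = None) -> BenchmarkDataset:
    """Generate a dataset from a plain config dict and a seed.

    The motif WM is regenerated from a seed derived from ``seed``, so
    (config, seed) fully determines the dataset.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    wm_seed = int(rng.integers(2**31))
    wm = generate_wm(
        cfg["width"], cfg["target_ic"], tolerance=cfg["ic_tolerance"],
        seed=wm_seed, label=cfg["wm_label"],
    )
    bg = None if cfg["background"] is None else np.asarray(cfg["background"], dtype=float)
    loss = LossSpec(frozenset(cfg["lost_species"]), frozenset(cfg["lost_genes"]))
    dsid = dataset_id or f"{cfg['space']}-{seed}"
    space = cfg["space"]
    if space == "coregulation":
        ds = simulate_coregulation_space(
            cfg["n_genes"], wm, ref_proximity=cfg["ref_proximity"],
            bg_length=cfg["bg_length"], dropout_k=cfg["dropout_k"],
            rng=rng, dataset_id=dsid, background=bg,
        )
    elif space in ("combined", "orthologous"):
        if cfg["tree"] is None:
            raise ValueError(f"{space} space requires a 'tree' Newick string")
        tree = parse_newick(cfg["tree"], branch_mode=cfg["branch_mode"])
        if space == "combined":
            ds = simulate_combined_space(
                cfg["n_genes"], wm, tree, loss=loss, bg_length=cfg["bg_length"],
                rng=rng, dataset_id=dsid, background=bg,
            )
        else:
            ds = simulate_orthologous_space(
                wm, tree, bg_length=cfg["bg_length"], rng=rng,
                dataset_id=dsid, loss=loss, background=bg,
            )
    else:
        raise ValueError(f"unknown space {space!r}")
    ds.config = cfg
    ds.seed = seed
    return ds


# ---------------------------------------------------------------------------
# persistence

_FASTA = "sequences.fasta"
_GFF3 = "sites.gff3"
_MANIFEST = "manifest.json"


def _seqid(r) -> str:
    return f"{r.dataset_id}|{r.species}|{r.gene}"


def write_dataset(ds: BenchmarkDataset, directory: str | Path) -> Path:
    """Write FASTA + ground-truth GFF3 + manifest JSON; returns the dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=_seqid(r), description="") for r in ds.records
    ]
    SeqIO.write(seq_records, directory / _FASTA, "fasta")
    with open(directory / _GFF3, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, s in enumerate(ds.sites):
            seqid = f"{ds.dataset_id}|{s.species}|{s.gene}"
            attrs = f"ID=site{k};wm_label={s.wm_label}"
            # GFF3 is 1-based inclusive: [start, end) -> start+1 .. end
            fh.write(
                f"{seqid}\tmotifbench\tTF_binding_site\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t{attrs}\n"
            )
    manifest = {
        "dataset_id": ds.dataset_id,
        "space": ds.space,
        "seed": ds.seed,
        "config": ds.config,
        "format_version": 1,
    }
    with open(directory / _MANIFEST, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return directory


def read_dataset(directory: str | Path) -> BenchmarkDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    with open(directory / _MANIFEST) as fh:
        manifest = json.load(fh)
    records = []
    for rec in SeqIO.parse(str(directory / _FASTA), "fasta"):
        dataset_id, species, gene = rec.id.split("|")
        records.append(SequenceRecord(dataset_id, species, gene, str(rec.seq)))
    sites = []
    with open(directory / _GFF3) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            _, species, gene = seqid.split("|")
            wm_label = ""
            for item in attrs.split(";"):
                if item.startswith("wm_label="):
                    wm_label = item.split("=", 1)[1]
            sites.append(
                GroundTruthSite(species, gene, int(start) - 1, int(end), strand, wm_label)
            )
    return BenchmarkDataset(
        manifest["dataset_id"], manifest["space"], records, sites,
        config=manifest.get("config", {}), seed=manifest.get("seed"),
    )
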