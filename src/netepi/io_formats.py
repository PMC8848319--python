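"""Domain types and readers/writers for every external format the pipeline touches.

Formats handled: PLINK 1 binary genotypes (.bed/.bim/.fam, SNP-major),
tab-separated SNP-gene mapping tables, gene-gene co-function edge lists with
evidence counts, GMT gene-set collections, covariate tables, and the TSV
result bundles the pipeline emits.

Conventions fixed here and relied on everywhere else:

* genotypes are additive dosages counting copies of allele A1, stored as
  ``int8`` with :data:`MISSING` (= -1) as the missing sentinel;
* phenotype is 0 (control) / 1 (case) internally; .fam codes 1/2 are
  converted on read, 0/-9 map to :data:`MISSING`;
* base-pair positions are 1-based and all genomic intervals are treated as
  closed ``[start, end]``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "FormatError",
    "ValidationError",
    "SnpRecord",
    "GenotypeDataset",
    "SnpGeneMap",
    "MappingEntry",
    "GeneNetwork",
    "GeneSetCollection",
    "read_plink",
    "write_plink",
    "read_mapping_table",
    "write_mapping_table",
    "read_network_table",
    "write_network_table",
    "read_gmt",
    "write_gmt",
    "read_covariates",
    "write_results",
]

#: Sentinel for a missing genotype call. Distinct from the valid dosages
#: {0, 1, 2}; arithmetic on missing entries is a bug unless an operation
#: explicitly declares complete-case handling.
MISSING: int = -1

#: Allowed provenance labels for a SNP-gene mapping entry.
MAPPING_SOURCES = ("positional", "eqtl", "chromatin")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Well-formed input whose content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP; A1 is the counted allele."""

    snp_id: str
    chromosome: str
    position: int  # 1-based bp
    allele_a1: str = "A"
    allele_a2: str = "B"

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("empty snp_id")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position} for {self.snp_id}")


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive-coded genotype matrix with phenotype and covariates.

    ``genotypes[i, j]`` counts copies of ``snps[j].allele_a1`` carried by
    ``sample_ids[i]`` and lies in {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    snps: list[SnpRecord]
    genotypes: np.ndarray
    phenotype: np.ndarray
    covariates: Optional[np.ndarray] = None
    covariate_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but genotype matrix has {n} rows"
            )
        if len(self.snps) != m:
            raise ValidationError(f"{len(self.snps)} SNP records but genotype matrix has {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValidationError("snp_ids are not unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("genotype entries outside {0,1,2,missing}")
        if self.phenotype.shape != (n,):
            raise ValidationError("phenotype length does not match sample count")
        if not np.isin(self.phenotype, (0, 1, MISSING)).all():
            raise ValidationError("phenotype entries outside {0,1,missing}")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim != 2 or self.covariates.shape[0] != n:
                raise ValidationError("covariate matrix shape does not match sample count")
            if self.covariate_names is not None and len(self.covariate_names) != self.covariates.shape[1]:
                raise ValidationError("covariate_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: j for j, s in enumerate(self.snps)}


@dataclass(frozen=True, order=True)
class MappingEntry:
    """One (snp, gene) assignment with its evidence source and optional tissue."""

    snp_id: str
    gene_id: str
    source: str
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.snp_id or not self.gene_id:
            raise ValidationError("empty snp_id or gene_id in mapping entry")
        if self.source not in MAPPING_SOURCES:
            raise ValidationError(
                f"unknown mapping source {self.source!r}; allowed: {'|'.join(MAPPING_SOURCES)}"
            )


@dataclass
class SnpGeneMap:
    """Many-to-many SNP <-> gene relation tagged with provenance."""

    entries: set[MappingEntry] = field(default_factory=set)

    def project(self) -> set[tuple[str, str]]:
        """The (snp, gene) relation with source/tissue discarded."""
        return {(e.snp_id, e.gene_id) for e in self.entries}

    def genes(self) -> set[str]:
        return {e.gene_id for e in self.entries}

    def snps_for_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for snp, gene in self.project():
            out.setdefault(gene, set()).add(snp)
        return out

    def __len__(self) -> int:
        return len(self.entries)


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Evidence-weighted, undirected gene-gene co-function network.

    Edges are stored under lexicographically sorted gene pairs. Self-loops
    are permitted on read but recorded in ``self_loops`` so downstream model
    filtering can drop them.
    """

    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    self_loops: set[str] = field(default_factory=set)

    def add_edge(self, gene_a: str, gene_b: str, evidence_count: int) -> None:
        if evidence_count < 1:
            raise ValidationError(f"evidence_count must be >= 1, got {evidence_count}")
        if gene_a == gene_b:
            self.self_loops.add(gene_a)
        key = _edge_key(gene_a, gene_b)
        # duplicate (A,B)/(B,A) rows merge keeping the maximum evidence
        self.edges[key] = max(self.edges.get(key, 0), evidence_count)

    def genes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. MSigDB pathways) read from GMT."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


# ---------------------------------------------------------------------------
# PLINK 1 binary genotypes
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit codes, SNP-major: 00 hom A1 (dosage 2), 01 missing, 10 het, 11 hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, 1: 2, 0: 3, MISSING: 1}


def read_plink(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK 1 fileset into a :class:`GenotypeDataset`.

    The .bed must be SNP-major. Fam phenotypes coded 1 (control) / 2 (case)
    become 0/1; 0 and -9 become missing. Sample and SNP order follow the
    .fam / .bim row order.
    """
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    if fam["iid"].duplicated().any():
        raise ValidationError("duplicate individual ids in fam")
    pheno = np.empty(len(fam), dtype=np.int8)
    for i, code in enumerate(fam["phenotype"].astype(int)):
        if code == 1:
            pheno[i] = 0
        elif code == 2:
            pheno[i] = 1
        elif code in (0, -9):
            pheno[i] = MISSING
        else:
            raise ValidationError(f"unknown fam phenotype code {code} (allowed: 1, 2, 0, -9)")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "position", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    snps = [
        SnpRecord(r.snp_id, r.chrom, int(r.position), r.a1, r.a2)
        for r in bim.itertuples()
    ]

    n, m = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if header[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad bed magic bytes")
    if len(header) < 3 or header[2] != 0x01:
        raise FormatError(f"{bed_path}: only SNP-major bed files are supported")
    bytes_per_snp = (n + 3) // 4
    if len(payload) != bytes_per_snp * m:
        raise FormatError(
            f"{bed_path}: payload is {len(payload)} bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, sample index advancing within each byte from LSB
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    geno = _CODE_TO_DOSAGE[codes.reshape(m, -1)[:, :n]].T  # samples x snps

    return GenotypeDataset(
        sample_ids=list(fam["iid"]),
        snps=snps,
        genotypes=geno,
        phenotype=pheno,
    )


def write_plink(dataset: GenotypeDataset, prefix: str) -> None:
    """Write a dataset as ``prefix``.bed/.bim/.fam (SNP-major bed)."""
    n, m = dataset.n_samples, dataset.n_snps
    with open(f"{prefix}.fam", "w") as fh:
        for sid, y in zip(dataset.sample_ids, dataset.phenotype):
            code = {0: 1, 1: 2, MISSING: -9}[int(y)]
            fh.write(f"{sid} {sid} 0 0 0 {code}\n")
    with open(f"{prefix}.bim", "w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\t{s.allele_a1}\t{s.allele_a2}\n")
    bytes_per_snp = (n + 3) // 4
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage % 4] = code  # MISSING=-1 -> index 3; dosage 0,1,2 at own index
    # disambiguate: index 3 is only reached via MISSING (-1 % 4); dosages are 0..2
    per_snp = lut[dataset.genotypes.T % 4]
    codes[:, :n] = per_snp
    packed = (
        codes.reshape(m, bytes_per_snp, 4)
        << (np.arange(4, dtype=np.uint8) * 2)[None, None, :]
    ).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# TSV / GMT readers
# ---------------------------------------------------------------------------


def read_mapping_table(path) -> SnpGeneMap:
    """Read a SNP-gene mapping TSV with columns snp_id, gene_id, source[, tissue]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "gene_id", "source"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: mapping table must have columns {sorted(required)}")
    has_tissue = "tissue" in df.columns
    entries: set[MappingEntry] = set()
    for row in df.itertuples(index=False):
        tissue = getattr(row, "tissue", None) if has_tissue else None
        if isinstance(tissue, float) and np.isnan(tissue):
            tissue = None
        entries.add(MappingEntry(row.snp_id, row.gene_id, row.source, tissue))
    return SnpGeneMap(entries)


def write_mapping_table(mapping: SnpGeneMap, path) -> None:
    rows = sorted(
        (e.snp_id, e.gene_id, e.source, e.tissue or "") for e in mapping.entries
    )
    pd.DataFrame(rows, columns=["snp_id", "gene_id", "source", "tissue"]).to_csv(
        path, sep="\t", index=False
    )


def read_network_table(path) -> GeneNetwork:
    """Read a gene-gene edge list TSV with columns gene_a, gene_b, evidence_count."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "evidence_count"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: network table must have columns {sorted(required)}")
    network = GeneNetwork()
    for row in df.itertuples(index=False):
        ev = row.evidence_count
        if isinstance(ev, float) and not float(ev).is_integer():
            raise ValidationError(f"non-integer evidence_count {ev} for ({row.gene_a},{row.gene_b})")
        try:
            ev = int(ev)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer evidence_count {ev!r}") from exc
        network.add_edge(row.gene_a, row.gene_b, ev)
    return network


def write_network_table(network: GeneNetwork, path) -> None:
    rows = sorted((a, b, ev) for (a, b), ev in network.edges.items())
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "evidence_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, genes...; genes deduplicated."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            if name in coll.sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in genes if g}
            if not genes:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            coll.sets[name] = genes
            coll.descriptions[name] = desc
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{genes}\n")


def read_covariates(path, sample_ids: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Read a covariate TSV (column ``sample_id`` + numeric columns), aligned to sample order."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: covariate table must have a sample_id column")
    df = df.set_index("sample_id")
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValidationError(f"{path}: covariates missing for samples {missing[:5]}")
    df = df.loc[list(sample_ids)]
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# Result bundle output
# ---------------------------------------------------------------------------


def write_results(bundle, out_dir) -> dict[str, str]:
    """Write a :class:`~netepi.pipeline.RunBundle` as TSV tables under ``out_dir``.

    Emits snp_models.tsv (significant SNP-pair tests), gene_models.tsv
    (per-gene-pair ATPM results), pathways.tsv, and threshold.tsv. Row
    ordering is deterministic: ascending p, then lexicographic ids, so two
    runs with the same config and seed produce byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    snp_rows = [
        (r.snp_a, r.snp_b, r.beta3, r.statistic, r.p, r.n_used)
        for r in bundle.significant_snp_models
    ]
    snp_rows.sort(key=lambda t: (t[4], t[0], t[1]))
    paths["snp_models"] = p = os.path.join(out_dir, "snp_models.tsv")
    pd.DataFrame(snp_rows, columns=["snp_a", "snp_b", "beta3", "stat", "p", "n_used"]).to_csv(
        p, sep="\t", index=False
    )

    gene_rows = []
    for g in bundle.gene_model_results:
        row = [g.gene_a, g.gene_b, g.n_snp_models]
        row += [g.pi0[tau] for tau in sorted(g.pi0)]
        row += [g.pi_star0, g.p0, g.significant]
        gene_rows.append(row)
    gene_rows.sort(key=lambda t: (t[-2], t[0], t[1]))
    taus = sorted(bundle.gene_model_results[0].pi0) if bundle.gene_model_results else []
    cols = ["gene_a", "gene_b", "n_snp_models"] + [f"pi0_tau{t}" for t in taus] + [
        "pi_star0", "p0", "significant",
    ]
    if not taus:
        cols = ["gene_a", "gene_b", "n_snp_models", "pi0_tau0.001", "pi0_tau0.01",
                "pi0_tau0.05", "pi_star0", "p0", "significant"]
    paths["gene_models"] = p = os.path.join(out_dir, "gene_models.tsv")
    pd.DataFrame(gene_rows, columns=cols).to_csv(p, sep="\t", index=False)

    path_rows = [
        (e.neighborhood_id, e.set_name, e.overlap, e.set_size, e.neighborhood_size,
         e.universe_size, e.p, e.threshold, e.significant)
        for e in bundle.enrichments
    ]
    path_rows.sort(key=lambda t: (t[6], t[0], t[1]))
    paths["pathways"] = p = os.path.join(out_dir, "pathways.tsv")
    pd.DataFrame(
        path_rows,
        columns=["neighborhood", "set_name", "overlap", "set_size",
                 "neighborhood_size", "universe_size", "p", "threshold", "significant"],
    ).to_csv(p, sep="\t", index=False)

    paths["threshold"] = p = os.path.join(out_dir, "threshold.tsv")
    if bundle.threshold_result is not None:
        t = bundle.threshold_result
        df = pd.DataFrame({"min_p": t.min_p_per_permutation})
        df.insert(0, "permutation", np.arange(1, len(t.min_p_per_permutation) + 1))
        df["threshold"] = t.threshold
        df["fwer_level"] = t.fwer_level
        df["seed"] = t.seed
    else:
        df = pd.DataFrame(columns=["permutation", "min_p", "threshold", "fwer_level", "seed"])
    df.to_csv(p, sep="\t", index=False)
    return paths
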