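"""Genotype matrix and model file input/output.

Coding conventions shared by every module in the package:

* A genotype call at a biallelic SNP is one of four symbols:
  ``HOM_MAJOR`` (``A_A``, both alleles are the designated major allele),
  ``HET`` (``A_B``), ``HOM_MINOR`` (``B_B``) and ``NOCALL`` (a failed
  measurement).  Internally calls are stored as a dense ``int8`` matrix with
  codes 0, 1, 2 and -1 respectively.
* "Major"/"minor" are dataset-relative names; the allele *characters* are what
  anchor a genotype's meaning.  Trained models therefore store each SNP's
  ``(allele_major, allele_minor)`` pair so that prediction on a dataset whose
  major/minor designation is flipped still resolves genotypes correctly.

The native text dialect is a UTF-8 tab-separated file::

    sample_id      rs1   rs2
    #chromosome    1     2
    #position      101   202
    #allele_major  A     C
    #allele_minor  G     T
    NA001          A_A   NoCall
    NA002          A_B   B_B

Any token outside the four-symbol alphabet is rejected with a
:class:`ParseError` naming the offending line; nothing is silently coerced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "HOM_MAJOR", "HET", "HOM_MINOR", "NOCALL",
    "GENOTYPE_TOKENS", "CODE_TO_TOKEN", "VALID_CHROMOSOMES", "AUTOSOMES",
    "ParseError", "ModelFormatError",
    "SnpRecord", "GenotypeMatrix", "PopulationLabels",
    "read_genotypes", "write_genotypes",
    "read_labels", "write_labels",
    "save_model", "load_model",
]

HOM_MAJOR: int = 0
HET: int = 1
HOM_MINOR: int = 2
NOCALL: int = -1

GENOTYPE_TOKENS: dict[str, int] = {
    "A_A": HOM_MAJOR, "A_B": HET, "B_B": HOM_MINOR, "NoCall": NOCALL,
}
CODE_TO_TOKEN: dict[int, str] = {v: k for k, v in GENOTYPE_TOKENS.items()}

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
VALID_CHROMOSOMES = AUTOSOMES | {"X", "Y", "MT", "UNKNOWN"}

#: class names reserved for the voting layer's sentinels
RESERVED_CLASS_NAMES = frozenset({"NO_CALL", "ABSTAIN"})

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """A genotype or label file violates the declared dialect."""


class ModelFormatError(ValueError):
    """A model file is truncated, corrupt, or of an unknown version."""


@dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP.

    Positions are 1-based, as in VCF.  ``chromosome`` must be one of
    "1".."22", "X", "Y", "MT" or "UNKNOWN".
    """

    snp_id: str
    chromosome: str
    position: int
    allele_major: str
    allele_minor: str

    def __post_init__(self) -> None:
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ValueError(
                f"SNP {self.snp_id!r}: invalid chromosome {self.chromosome!r}")
        if self.position < 1:
            raise ValueError(f"SNP {self.snp_id!r}: position must be >= 1")
        if len(self.allele_major) != 1 or len(self.allele_minor) != 1:
            raise ValueError(f"SNP {self.snp_id!r}: alleles must be single characters")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"SNP {self.snp_id!r}: major and minor allele identical")


def normalize_chromosome(raw: str) -> str:
    """Map a chromosome string onto the package's canonical names.

    Strips a leading ``chr`` prefix and maps ``M`` to ``MT``; anything not in
    "1".."22"/"X"/"Y"/"MT" becomes ``UNKNOWN``.
    """
    c = raw.removeprefix("chr")
    if c == "M":
        c = "MT"
    return c if c in VALID_CHROMOSOMES else "UNKNOWN"


@dataclass
class GenotypeMatrix:
    """A samples x SNPs matrix of categorical genotype calls.

    ``calls[i, j]`` is the call of sample ``samples[i]`` at SNP ``snps[j]``,
    coded 0/1/2/-1 (HOM_MAJOR/HET/HOM_MINOR/NOCALL).
    """

    samples: tuple[str, ...]
    snps: tuple[SnpRecord, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.snps = tuple(self.snps)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.calls, (HOM_MAJOR, HET, HOM_MINOR, NOCALL))
        if bad.any():
            raise ValueError("calls contain codes outside {0, 1, 2, -1}")
        self._snp_index = {s.snp_id: j for j, s in enumerate(self.snps)}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def sample_calls(self, sample_id: str) -> dict[str, int]:
        """Genotype mapping ``snp_id -> code`` for one sample."""
        row = self.calls[self.sample_index(sample_id)]
        return {s.snp_id: int(row[j]) for j, s in enumerate(self.snps)}

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(tuple(self.samples[i] for i in idx),
                              self.snps, self.calls[idx, :])

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(self.samples,
                              tuple(self.snps[j] for j in idx),
                              self.calls[:, idx])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.samples == other.samples and self.snps == other.snps
                and np.array_equal(self.calls, other.calls))


@dataclass(frozen=True)
class PopulationLabels:
    """Per-sample population assignment with a fixed class ordering.

    ``class_order`` fixes the deterministic tie-break used throughout the
    package (vote ties, leaf-label ties): earlier classes win.
    """

    class_order: tuple[str, ...]
    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_order", tuple(self.class_order))
        object.__setattr__(self, "assignment", dict(self.assignment))
        if len(set(self.class_order)) != len(self.class_order):
            raise ValueError("duplicate class names in class_order")
        bad = RESERVED_CLASS_NAMES & set(self.class_order)
        if bad:
            raise ValueError(f"class names {sorted(bad)} are reserved")
        extra = set(self.assignment.values()) - set(self.class_order)
        if extra:
            raise ValueError(f"assigned classes {sorted(extra)} not in class_order")

    def encoded(self, sample_ids) -> np.ndarray:
        """Integer class indices (into class_order) for the given samples."""
        lut = {c: i for i, c in enumerate(self.class_order)}
        return np.array([lut[self.assignment[s]] for s in sample_ids], dtype=np.intp)


# ---------------------------------------------------------------------------
# native TSV dialect
# ---------------------------------------------------------------------------

_META_ROWS = ("#chromosome", "#position", "#allele_major", "#allele_minor")


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    """Write a matrix in the native tab-separated dialect (lossless)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        ids = matrix.snp_ids
        fh.write("\t".join(("sample_id",) + ids) + "\n")
        fh.write("\t".join(("#chromosome",) + tuple(s.chromosome for s in matrix.snps)) + "\n")
        fh.write("\t".join(("#position",) + tuple(str(s.position) for s in matrix.snps)) + "\n")
        fh.write("\t".join(("#allele_major",) + tuple(s.allele_major for s in matrix.snps)) + "\n")
        fh.write("\t".join(("#allele_minor",) + tuple(s.allele_minor for s in matrix.snps)) + "\n")
        for i, sample in enumerate(matrix.samples):
            toks = [CODE_TO_TOKEN[int(c)] for c in matrix.calls[i]]
            fh.write("\t".join([sample] + toks) + "\n")


def _read_native_tsv(path: Path) -> GenotypeMatrix:
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[0] != "sample_id":
        raise ParseError(f"{path} line 1: header must start with 'sample_id'")
    snp_ids = header[1:]
    ncol = len(header)
    if len(lines) < 1 + len(_META_ROWS):
        raise ParseError(f"{path}: missing metadata block")
    meta: dict[str, list[str]] = {}
    for k, name in enumerate(_META_ROWS):
        lineno = 2 + k
        row = lines[1 + k].split("\t")
        if row[0] != name:
            raise ParseError(f"{path} line {lineno}: expected metadata row {name!r}, "
                             f"got {row[0]!r}")
        if len(row) != ncol:
            raise ParseError(f"{path} line {lineno}: expected {ncol} columns, got {len(row)}")
        meta[name] = row[1:]
    try:
        snps = tuple(
            SnpRecord(sid, meta["#chromosome"][j], int(meta["#position"][j]),
                      meta["#allele_major"][j], meta["#allele_minor"][j])
            for j, sid in enumerate(snp_ids))
    except ValueError as exc:
        raise ParseError(f"{path}: invalid SNP metadata: {exc}") from exc

    samples: list[str] = []
    rows: list[list[int]] = []
    for k, line in enumerate(lines[1 + len(_META_ROWS):]):
        lineno = 2 + len(_META_ROWS) + k
        if not line:
            continue
        row = line.split("\t")
        if len(row) != ncol:
            raise ParseError(f"{path} line {lineno}: expected {ncol} columns, got {len(row)}")
        samples.append(row[0])
        codes = []
        for tok in row[1:]:
            if tok not in GENOTYPE_TOKENS:
                raise ParseError(f"{path} line {lineno}: unknown genotype token {tok!r}")
            codes.append(GENOTYPE_TOKENS[tok])
        rows.append(codes)
    calls = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(snps)), dtype=np.int8))
    try:
        return GenotypeMatrix(tuple(samples), snps, calls)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    """Read genotypes from a VCF 4.x file (uncompressed or bgzipped).

    REF is taken as the major-allele character and the first ALT as the minor.
    Multi-allelic sites and half-calls are coerced to NOCALL with a warning:
    the classifier's alphabet is strictly the four symbols.
    """
    from cyvcf2 import VCF  # local import: only needed for this dialect

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    n_coerced = 0
    seen: set[str] = set()
    for var in vcf:
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        if sid in seen:
            raise ParseError(f"{path}: duplicate SNP id {sid!r}")
        seen.add(sid)
        alts = var.ALT
        multi = len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1
        minor = alts[0][0] if alts and len(alts[0]) == 1 else "N"
        if multi:
            minor = "N" if var.REF != "N" else "X"
        snps.append(SnpRecord(sid, normalize_chromosome(var.CHROM), var.POS,
                              var.REF[0], minor))
        col = np.full(len(samples), NOCALL, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a = gt[:-1]  # last element is the phased flag
            if multi or any(x < 0 for x in a) or any(x > 1 for x in a):
                n_coerced += int(multi or any(x > 1 for x in a))
                continue
            col[i] = int(sum(a))
        columns.append(col)
    if n_coerced:
        warnings.warn(f"{path}: {n_coerced} multi-allelic or out-of-alphabet "
                      f"genotypes coerced to NoCall", stacklevel=3)
    calls = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples, tuple(snps), calls)


def read_genotypes(path, format: str = "native_tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``path``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"native_tsv"`` (the package dialect) or ``"vcf"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native_tsv":
        return _read_native_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# population label files
# ---------------------------------------------------------------------------

def write_labels(labels: PopulationLabels, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tpopulation\n")
        for sample, cls in labels.assignment.items():
            fh.write(f"{sample}\t{cls}\n")


def read_labels(path, class_order=None) -> PopulationLabels:
    """Read a two-column ``sample_id<TAB>population`` file.

    ``class_order`` defaults to first-appearance order in the file.
    """
    path = Path(path)
    assignment: dict[str, str] = {}
    order: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("sample_id")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path} line {lineno}: expected 2 columns, got {len(parts)}")
            sample, cls = parts
            if sample in assignment:
                raise ParseError(f"{path} line {lineno}: duplicate sample id {sample!r}")
            assignment[sample] = cls
            if cls not in order:
                order.append(cls)
    return PopulationLabels(tuple(class_order) if class_order else tuple(order),
                            assignment)


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

def _node_to_dict(node) -> dict:
    if node.is_leaf:
        return {"kind": "leaf", "label": node.label,
                "class_counts": [int(c) for c in node.class_counts]}
    return {"kind": "internal", "snp_id": node.snp_id,
            "left_genotypes": sorted(int(g) for g in node.left_genotypes),
            "class_counts": [int(c) for c in node.class_counts],
            "left": _node_to_dict(node.left), "right": _node_to_dict(node.right)}


def _node_from_dict(d: dict, class_order):
    from .cart import TreeNode
    try:
        counts = tuple(int(c) for c in d["class_counts"])
        if d["kind"] == "leaf":
            return TreeNode.leaf(counts, class_order, label=d["label"])
        if d["kind"] == "internal":
            return TreeNode.internal(
                d["snp_id"], frozenset(int(g) for g in d["left_genotypes"]),
                _node_from_dict(d["left"], class_order),
                _node_from_dict(d["right"], class_order), counts)
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed tree node: {exc}") from exc
    raise ModelFormatError(f"unknown node kind {d.get('kind')!r}")


def save_model(ensemble, path) -> None:
    """Serialize a trained :class:`~ethnopred.ensemble.DisjointEnsemble`.

    The file is plain JSON with an explicit ``format_version`` so future
    revisions can refuse (rather than misread) incompatible files.  The
    round trip ``load_model(save_model(e)) == e`` is exact: every field is
    integer- or string-valued.
    """
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "class_order": list(ensemble.class_order),
        "snp_alleles": {sid: list(pair) for sid, pair in ensemble.snp_alleles.items()},
        "meta": ensemble.meta,
        "trees": [_node_to_dict(t.root) for t in ensemble.trees],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path):
    """Load a model file written by :func:`save_model`."""
    from .cart import DecisionTree
    from .ensemble import DisjointEnsemble

    path = Path(path)
    try:
        with path.open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"{path}: cannot parse model file: {exc}") from exc
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ModelFormatError(f"{path}: not a model file (no format_version)")
    if doc["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported format_version {doc['format_version']!r}")
    try:
        class_order = tuple(doc["class_order"])
        trees = tuple(
            DecisionTree(_node_from_dict(td, class_order), class_order)
            for td in doc["trees"])
        snp_alleles = {sid: (p[0], p[1]) for sid, p in doc["snp_alleles"].items()}
        meta = doc["meta"]
    except (KeyError, TypeError, IndexError) as exc:
        raise ModelFormatError(f"{path}: malformed model document: {exc}") from exc
    return DisjointEnsemble(trees=trees, class_order=class_order,
                            snp_alleles=snp_alleles, meta=meta)
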