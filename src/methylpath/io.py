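"""Readers and writers for methylome call tables, annotations and run configuration.

Conventions used throughout the package:

* Internal coordinates are **0-based half-open** everywhere. Conversion happens
  only at I/O boundaries: GFF3 is 1-based inclusive, BED is already 0-based
  half-open, and cytosine call tables carry 1-based positions (allc/CX-report
  dialect).
* Cytosine calls are strand-resolved and never collapsed across strands. A
  feature's cytosines are all calls overlapping ``[start, end)`` regardless of
  strand, which is the natural treatment for the asymmetric CHH context.
* Cytosine tables are kept as :class:`pandas.DataFrame` objects with columns
  ``chrom, pos, strand, context, n_meth, n_total``, sorted by (chrom, pos).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
import yaml

CONTEXTS = ("CG", "CHG", "CHH")

#: columns of a cytosine call table, in order
CYTOSINE_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_total")


class FormatError(ValueError):
    """A file does not conform to the expected table layout."""


class ValidationError(ValueError):
    """A file parses but carries impossible values."""


class CytosineCall(NamedTuple):
    """One strand-resolved cytosine with read counts.

    ``pos`` is 1-based, as in allc/CX-report input.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int


@dataclass(frozen=True)
class Feature:
    """A genomic feature (TE, gene or DMR) in 0-based half-open coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "TE"
    family: str = ""
    superfamily: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"feature {self.id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"feature {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# cytosine call tables
# ---------------------------------------------------------------------------

def read_cytosine_table(path, context_filter: Optional[str] = None) -> pd.DataFrame:
    """Read an allc/CX-report-style TSV of per-cytosine methylation calls.

    Parameters
    ----------
    path:
        TSV with columns chrom, pos (1-based), strand, context, n_meth,
        n_total. A header line is tolerated and detected automatically.
    context_filter:
        If given (one of CG/CHG/CHH), only calls of that context are returned.

    Returns
    -------
    DataFrame sorted by (chrom, pos) with the canonical column names.
    """
    if context_filter is not None and context_filter not in CONTEXTS:
        raise ValueError(f"context_filter must be one of {CONTEXTS}")
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=list(CYTOSINE_COLUMNS), dtype=str,
    )
    if df.empty:
        return _empty_cytosine_frame()
    # tolerate a header row
    if df.iloc[0]["pos"] in ("pos", "position"):
        df = df.iloc[1:].reset_index(drop=True)
    if df[["chrom", "pos", "strand", "context", "n_meth", "n_total"]].isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise FormatError(f"{path}: line {bad}: expected 6 tab-separated columns")
    try:
        df["pos"] = df["pos"].astype("int64")
        df["n_meth"] = df["n_meth"].astype("int64")
        df["n_total"] = df["n_total"].astype("int64")
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count or position field: {exc}") from None
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        raise FormatError(
            f"{path}: line {line}: context {df.loc[bad_ctx.idxmax(), 'context']!r} "
            f"not one of {CONTEXTS}"
        )
    if (df["pos"] < 1).any():
        raise ValidationError(f"{path}: positions must be >= 1")
    over = df["n_meth"] > df["n_total"]
    if over.any():
        row = df.loc[over.idxmax()]
        raise ValidationError(
            f"{path}: {row.chrom}:{row.pos}: n_meth ({row.n_meth}) exceeds "
            f"n_total ({row.n_total})"
        )
    if (df[["n_meth", "n_total"]] < 0).any().any():
        raise ValidationError(f"{path}: negative read counts")
    if context_filter is not None:
        df = df[df["context"] == context_filter]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _empty_cytosine_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype="int64"),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype="int64"),
            "n_total": pd.Series(dtype="int64"),
        }
    )


def write_cytosine_table(df: pd.DataFrame, path) -> None:
    """Write a cytosine call table in the dialect :func:`read_cytosine_table` reads."""
    df.to_csv(path, sep="\t", header=False, index=False, columns=list(CYTOSINE_COLUMNS))


def iter_calls(df: pd.DataFrame) -> Iterator[CytosineCall]:
    """Yield the rows of a call table as :class:`CytosineCall` tuples."""
    for row in df.itertuples(index=False):
        yield CytosineCall(row.chrom, row.pos, row.strand, row.context,
                           row.n_meth, row.n_total)


# ---------------------------------------------------------------------------
# feature annotations
# ---------------------------------------------------------------------------

def _parse_gff_attributes(raw: str) -> dict:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, val = chunk.partition("=")
        elif " " in chunk:  # GTF-ish fallback
            key, _, val = chunk.partition(" ")
            val = val.strip('"')
        else:
            continue
        attrs[key.strip()] = val.strip()
    return attrs


def read_features(path, kind: str = "TE") -> list[Feature]:
    """Read features from GFF3 (1-based inclusive) or BED (0-based half-open).

    The format is chosen by file extension (.gff/.gff3/.gtf vs .bed).
    Coordinates are normalized to the internal 0-based half-open convention.
    ``family``/``superfamily`` are taken from the GFF attribute column when
    present (keys family/Family/Alias and superfamily/Super_Family).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3", ".gtf"):
        return _read_gff3(path, kind)
    if suffix == ".bed":
        return _read_bed(path, kind)
    raise FormatError(f"{path}: unrecognized annotation extension {suffix!r}")


def _read_gff3(path: Path, kind: str) -> list[Feature]:
    feats: list[Feature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF columns")
            chrom, _src, _type, start, end, _score, strand, _frame, raw_attrs = parts[:9]
            attrs = _parse_gff_attributes(raw_attrs)
            fid = attrs.get("ID") or attrs.get("Name") or f"{chrom}:{start}-{end}"
            start0, end0 = int(start) - 1, int(end)
            if start0 >= end0:
                raise ValidationError(f"{path}: line {lineno}: end < start for {fid}")
            if fid in seen:
                raise ValidationError(f"{path}: duplicate feature id {fid!r}")
            seen.add(fid)
            feats.append(Feature(
                id=fid, chrom=chrom, start=start0, end=end0,
                strand=strand if strand in ("+", "-") else ".",
                kind=kind,
                family=attrs.get("family", attrs.get("Family", attrs.get("Alias", ""))),
                superfamily=attrs.get("superfamily", attrs.get("Super_Family", "")),
            ))
    return feats


def _read_bed(path: Path, kind: str) -> list[Feature]:
    feats: list[Feature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            fid = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: end <= start for {fid}")
            if fid in seen:
                raise ValidationError(f"{path}: duplicate feature id {fid!r}")
            seen.add(fid)
            family = parts[6] if len(parts) > 6 else ""
            superfamily = parts[7] if len(parts) > 7 else ""
            feats.append(Feature(id=fid, chrom=chrom, start=start, end=end,
                                 strand=strand, kind=kind, family=family,
                                 superfamily=superfamily))
    return feats


def write_features_bed(features: Sequence[Feature], path) -> None:
    """Write features as BED6 plus family/superfamily columns (round-trips)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}"
                f"\t{f.family}\t{f.superfamily}\n"
            )


def write_features_gff3(features: Sequence[Feature], path, source: str = "methylpath") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id}"
            if f.family:
                attrs += f";family={f.family}"
            if f.superfamily:
                attrs += f";superfamily={f.superfamily}"
            ftype = {"TE": "transposable_element", "gene": "gene"}.get(f.kind, f.kind)
            fh.write(
                f"{f.chrom}\t{source}\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# genotype manifest and pipeline configuration
# ---------------------------------------------------------------------------

#: canonical role keys used by the pathway classifier
CLASSIFIER_ROLES = ("ref", "polIV", "rdr6", "dcl3", "polV", "polIV_rdr6")

#: role names accepted in a silent-background (wt Col) manifest
SILENT_ROLES = ("wt", "polIV", "rdr2", "dcl3", "rdr6", "polV", "polIV_rdr6",
                "ago1", "ago6", "drm2")
#: role names accepted in an active-background (ddm1) manifest
ACTIVE_ROLES = tuple(
    "ddm1" if r == "wt" else f"ddm1_{r}" for r in SILENT_ROLES
)

_REQUIRED = {
    "silent": ("wt", "polIV", "rdr6", "dcl3", "polV", "polIV_rdr6"),
    "active": ("ddm1", "ddm1_polIV", "ddm1_rdr6", "ddm1_dcl3", "ddm1_polV",
               "ddm1_polIV_rdr6"),
}


def required_roles(background: str) -> tuple[str, ...]:
    """Role names the classifier needs for the given background."""
    try:
        return _REQUIRED[background]
    except KeyError:
        raise ValueError(f"background must be 'silent' or 'active', got {background!r}")


def canonical_role(role: str, background: str) -> str:
    """Map a manifest role name to its classifier key (ref, polIV, ...)."""
    if background == "active":
        if role == "ddm1":
            return "ref"
        role = role.removeprefix("ddm1_")
    elif role == "wt":
        return "ref"
    return role


@dataclass
class GenotypeManifest:
    """Which cytosine table belongs to which genotype role, per background."""

    background: str  # "silent" or "active"
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        accepted = SILENT_ROLES if self.background == "silent" else ACTIVE_ROLES
        required = required_roles(self.background)
        unknown = sorted(set(self.paths) - set(accepted))
        if unknown:
            raise ValidationError(
                f"unknown genotype role(s) {unknown}; accepted roles for "
                f"{self.background} background: {list(accepted)}"
            )
        missing = sorted(set(required) - set(self.paths))
        if missing:
            raise ValidationError(
                f"manifest ({self.background}) missing required role(s): {missing}"
            )

    @property
    def ref_role(self) -> str:
        return "wt" if self.background == "silent" else "ddm1"

    def classifier_paths(self) -> dict[str, str]:
        """Paths keyed by canonical classifier role (ref, polIV, ...)."""
        return {canonical_role(r, self.background): p
                for r, p in self.paths.items()
                if r in required_roles(self.background)}


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with its default.

    Defaults encode the published analysis settings: a TE is "no CHH" below
    1 % reference CHH methylation; pathway loss means a strict >2-fold drop;
    DMSs at most 250 bp apart chain into a DMR of >=4 DMSs; meta-plots use
    100 bp bins over 2 kb flanks; full-length TEs exceed 80 % of their
    consensus length and fragments stay under 20 %; LTR-domain hits must
    cover >90 % of the domain model; LTRs more than 50 bp internal are
    discarded; cleavage sites need p < 0.05; competence needs 1 RPM of
    mRNA or 10 RPM of 21-22 nt siRNA or any cleavage evidence.
    """

    no_chh_threshold: float = 0.01
    fold_loss_threshold: float = 2.0
    dms_alpha: float = 0.01
    dmr_max_gap: int = 250
    dmr_min_dms: int = 4
    metaplot_bin: int = 100
    metaplot_flank: int = 2000
    metaplot_body_cap: int = 3000
    full_length_min: float = 0.80
    fragment_max: float = 0.20
    domain_min_coverage: float = 0.90
    ltr_edge_max_dist: int = 50
    cleavage_alpha: float = 0.05
    competence_rna_rpm: float = 1.0
    competence_sirna_rpm: float = 10.0
    sirna_size_min: int = 18
    sirna_size_max: int = 28
    secondary_sizes: tuple = (21, 22)
    read_length: int = 150
    min_covered_cytosines: int = 1

    def __post_init__(self) -> None:
        for name in ("no_chh_threshold", "fold_loss_threshold", "dms_alpha",
                     "dmr_max_gap", "dmr_min_dms", "metaplot_bin",
                     "metaplot_flank", "full_length_min", "fragment_max",
                     "domain_min_coverage", "cleavage_alpha",
                     "competence_rna_rpm", "competence_sirna_rpm",
                     "read_length", "min_covered_cytosines"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be strictly positive")
        if self.fragment_max >= self.full_length_min:
            raise ValidationError("config: fragment_max must be < full_length_min")
        if isinstance(self.secondary_sizes, list):
            object.__setattr__(self, "secondary_sizes", tuple(self.secondary_sizes))


def read_manifest(path) -> tuple[GenotypeManifest, PipelineConfig]:
    """Read a YAML run configuration naming genotype tables and thresholds.

    Layout::

        background: silent
        genotypes:
          wt: wt.allc.tsv
          polIV: nrpd1.allc.tsv
          ...
        params:            # optional overrides of PipelineConfig fields
          fold_loss_threshold: 3.0

    Relative table paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "background" not in raw or "genotypes" not in raw:
        raise FormatError(f"{path}: config needs 'background' and 'genotypes' keys")
    base = path.parent
    paths = {role: str((base / p)) if not Path(p).is_absolute() else str(p)
             for role, p in raw["genotypes"].items()}
    manifest = GenotypeManifest(background=raw["background"], paths=paths)
    params = raw.get("params") or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(params) - known)
    if unknown:
        raise ValidationError(f"{path}: unknown config parameter(s): {unknown}")
    config = PipelineConfig(**params)
    return manifest, config


def write_manifest(manifest: GenotypeManifest, config: PipelineConfig, path) -> None:
    doc = {
        "background": manifest.background,
        "genotypes": dict(manifest.paths),
        "params": {
            f.name: (list(v) if isinstance(v := getattr(config, f.name), tuple) else v)
            for f in dataclasses.fields(PipelineConfig)
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
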