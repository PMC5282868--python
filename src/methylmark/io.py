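"""Readers, writers and array-level QC for methylation data.

Three on-disk artefacts are handled here:

* **beta matrices** — loci x samples tables of methylation fractions
  (``beta`` values in [0, 1]), TSV with a sample-id header row, locus ids in
  the first column and ``NA`` for missing cells;
* **sample sheets** — TSV mapping each sample id to a biological group
  (``cancer``, ``normal_urothelium``, ``blood``, ``noncancer_urine``,
  ``urine_case``) with optional tumour stage and grade;
* **amplicon panels** — a BED file of single-base CpG targets, a FASTA of
  amplicon sequences (genomic placement in the description as
  ``loc=chrom:start-end``, 1-based inclusive) and a TSV sidecar of primer
  spans (0-based half-open offsets within each amplicon).

All genomic coordinates are kept 1-based internally (position of the CpG
cytosine on the forward strand); BED's 0-based half-open convention is
translated at the file boundary only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLE_GROUPS = frozenset(
    {"cancer", "normal_urothelium", "blood", "noncancer_urine", "urine_case"}
)
#: groups treated as disease-positive by the classifier
CANCER_GROUPS = frozenset({"cancer", "urine_case"})
#: the non-cancer reference classes the discovery filter constrains
NONCANCER_REFERENCE_GROUPS = ("normal_urothelium", "blood", "noncancer_urine")

AMPLICON_LENGTH_RANGE = (120, 300)


class FormatError(ValueError):
    """A file violates the expected tabular format or value domain."""


class PanelError(ValueError):
    """A panel definition is internally inconsistent."""


class DimensionError(ValueError):
    """Two matrices that must be aligned are not."""


# ---------------------------------------------------------------------------
# beta matrices
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Loci x samples matrix of methylation beta fractions.

    ``values`` is a float DataFrame indexed by locus id with one column per
    sample; missing measurements are ``NaN`` and are never silently imputed
    here.  ``coords`` optionally carries per-locus genomic coordinates
    (columns ``chromosome``, ``position``, ``strand``; 1-based forward-strand
    position of the CpG cytosine).
    """

    values: pd.DataFrame
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise FormatError("duplicate locus ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in beta matrix")
        arr = self.values.to_numpy()
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise FormatError("beta values must lie in [0, 1]")
        if self.coords is not None:
            self.coords = self.coords.reindex(self.values.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_loci(self, locus_ids) -> "BetaMatrix":
        locus_ids = list(locus_ids)
        missing = set(locus_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown loci: {sorted(missing)[:5]}")
        coords = self.coords.loc[locus_ids] if self.coords is not None else None
        return BetaMatrix(self.values.loc[locus_ids].copy(), coords)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)[:5]}")
        coords = self.coords.copy() if self.coords is not None else None
        return BetaMatrix(self.values[sample_ids].copy(), coords)


_NA_TOKENS = {"NA", "NaN", "nan", ""}


def read_beta_matrix(path) -> BetaMatrix:
    """Read a beta-matrix TSV (header = sample ids, first column = locus id).

    Raises :class:`FormatError` for duplicate ids, non-numeric non-NA cells
    or values outside [0, 1].
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate sample ids")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = header  # undo pandas' duplicate-name mangling
    if raw.index.has_duplicates:
        raise FormatError(f"{path}: duplicate locus ids")
    num = raw.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = num.isna() & ~raw.isin(_NA_TOKENS)
    if bad.to_numpy().any():
        loc = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at locus {raw.index[loc[0]]!r}, "
            f"sample {raw.columns[loc[1]]!r}"
        )
    return BetaMatrix(num)


def write_beta_matrix(betas: BetaMatrix, path) -> None:
    betas.values.to_csv(
        path, sep="\t", na_rep="NA", index_label="locus_id", float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample -> group assignment with optional tumour stage/grade.

    ``table`` is indexed by sample id with a mandatory ``group`` column and
    optional ``stage`` (``Ta-T1`` / ``T2-T4``) and ``grade`` (``low`` /
    ``high``) columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample ids in sample sheet")
        if "group" not in self.table.columns:
            raise FormatError("sample sheet lacks a 'group' column")
        bad = set(self.table["group"]) - SAMPLE_GROUPS
        if bad:
            raise FormatError(f"unknown sample groups: {sorted(bad)}")
        for col in ("stage", "grade"):
            if col not in self.table.columns:
                self.table[col] = pd.NA

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "group"]

    def samples_in(self, *groups: str) -> list[str]:
        mask = self.table["group"].isin(groups)
        return list(self.table.index[mask])

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].copy())


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


# ---------------------------------------------------------------------------
# amplicon panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    amplicon_id: str
    sequence: str
    chromosome: str
    start: int  # 1-based genomic coordinate of sequence[0]
    primer_spans: tuple[tuple[int, int], ...] = ()  # 0-based half-open offsets

    @property
    def end(self) -> int:
        """1-based inclusive genomic coordinate of the last base."""
        return self.start + len(self.sequence) - 1

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetLocus:
    locus_id: str
    chromosome: str
    position: int  # 1-based forward-strand position of the CpG cytosine
    amplicon_id: str
    cpg_offset: int  # 0-based offset of the CpG cytosine within the amplicon
    gene: str | None = None


@dataclass
class PanelDefinition:
    """The target-locus set: CpG coordinates, amplicons and primer regions."""

    loci: list[TargetLocus]
    amplicons: dict[str, Amplicon]

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise PanelError("duplicate locus ids in panel")
        for amp in self.amplicons.values():
            n = len(amp.sequence)
            if not AMPLICON_LENGTH_RANGE[0] <= n <= AMPLICON_LENGTH_RANGE[1]:
                warnings.warn(
                    f"amplicon {amp.amplicon_id} length {n} outside "
                    f"{AMPLICON_LENGTH_RANGE}",
                    stacklevel=2,
                )
        for loc in self.loci:
            amp = self.amplicons.get(loc.amplicon_id)
            if amp is None:
                raise PanelError(f"{loc.locus_id}: unknown amplicon {loc.amplicon_id}")
            seq = amp.sequence.upper()
            o = loc.cpg_offset
            if not (0 <= o < len(seq) - 1 and seq[o] == "C" and seq[o + 1] == "G"):
                raise PanelError(
                    f"{loc.locus_id}: offset {o} in {loc.amplicon_id} is not a CpG"
                )
            for s, e in amp.primer_spans:
                if s <= o < e or s <= o + 1 < e:
                    raise PanelError(
                        f"{loc.locus_id}: CpG at offset {o} overlaps primer span "
                        f"({s}, {e}) of {loc.amplicon_id}"
                    )

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def amplicon_for(self, locus: TargetLocus) -> Amplicon:
        return self.amplicons[locus.amplicon_id]

    def loci_of(self, amplicon_id: str) -> list[TargetLocus]:
        return [l for l in self.loci if l.amplicon_id == amplicon_id]


_LOC_RE = re.compile(r"loc=(\S+):(\d+)-(\d+)")


def read_panel(bed_path, fasta_path, primers_path=None) -> PanelDefinition:
    """Assemble a :class:`PanelDefinition` from BED + FASTA (+ primer TSV).

    BED records are 0-based half-open single-base CpG positions, locus id in
    the name column; each locus must fall inside exactly one amplicon whose
    genomic placement is read from the FASTA description (``loc=chr:start-end``).
    """
    primer_spans: dict[str, list[tuple[int, int]]] = {}
    if primers_path is not None:
        pdf = pd.read_csv(primers_path, sep="\t", dtype={"amplicon_id": str})
        for _, row in pdf.iterrows():
            primer_spans.setdefault(str(row["amplicon_id"]), []).append(
                (int(row["start"]), int(row["end"]))
            )

    amplicons: dict[str, Amplicon] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = _LOC_RE.search(rec.description)
        if not m:
            raise PanelError(
                f"amplicon {rec.id}: no loc=chrom:start-end in FASTA header"
            )
        amplicons[rec.id] = Amplicon(
            amplicon_id=rec.id,
            sequence=str(rec.seq).upper(),
            chromosome=m.group(1),
            start=int(m.group(2)),
            primer_spans=tuple(primer_spans.get(rec.id, ())),
        )

    loci: list[TargetLocus] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"BED line has <4 columns: {line!r}")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end != start + 1:
                raise FormatError(f"{name}: BED record is not single-base")
            position = start + 1  # 0-based half-open -> 1-based
            gene = fields[6] if len(fields) > 6 and fields[6] != "." else None
            hit = None
            for amp in amplicons.values():
                if amp.chromosome == chrom and amp.start <= position <= amp.end:
                    hit = amp
                    break
            if hit is None:
                raise PanelError(f"{name}: no amplicon contains {chrom}:{position}")
            loci.append(
                TargetLocus(
                    locus_id=name,
                    chromosome=chrom,
                    position=position,
                    amplicon_id=hit.amplicon_id,
                    cpg_offset=position - hit.start,
                    gene=gene,
                )
            )
    return PanelDefinition(loci=loci, amplicons=amplicons)


def write_panel(panel: PanelDefinition, bed_path, fasta_path, primers_path=None) -> None:
    with open(bed_path, "w") as fh:
        for loc in panel.loci:
            gene = loc.gene or "."
            fh.write(
                f"{loc.chromosome}\t{loc.position - 1}\t{loc.position}\t"
                f"{loc.locus_id}\t0\t+\t{gene}\n"
            )
    records = [
        SeqRecord(
            Seq(a.sequence),
            id=a.amplicon_id,
            description=f"loc={a.chromosome}:{a.start}-{a.end}",
        )
        for a in panel.amplicons.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if primers_path is not None:
        rows = [
            {"amplicon_id": a.amplicon_id, "start": s, "end": e}
            for a in panel.amplicons.values()
            for s, e in a.primer_spans
        ]
        pd.DataFrame(rows, columns=["amplicon_id", "start", "end"]).to_csv(
            primers_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# probe QC
# ---------------------------------------------------------------------------


def qc_filter_probes(
    betas: BetaMatrix,
    snp_probes,
    detection_p: pd.DataFrame,
    p_max: float = 0.01,
) -> BetaMatrix:
    """Array-level probe QC: drop SNP-containing probes and probes not
    detected above background in every sample (detection p < ``p_max``).

    ``detection_p`` must be aligned cell-for-cell with ``betas``; the
    returned matrix is restricted to surviving loci (idempotent).
    """
    if not (
        detection_p.index.equals(betas.values.index)
        and detection_p.columns.equals(betas.values.columns)
    ):
        raise DimensionError("detection p-value matrix is not aligned with betas")
    snp = set(snp_probes)
    keep = ~betas.values.index.isin(snp) & (detection_p < p_max).all(axis=1).to_numpy()
    return betas.subset_loci(betas.values.index[keep])
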