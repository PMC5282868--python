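"""Per-locus methylation quantification from targeted bisulfite amplicon reads.

Pipeline: 3' adapter trimming -> in-silico bisulfite conversion of the
amplicon panel into four strand frames -> ungapped read-to-amplicon
assignment -> per-CpG methylated/unmethylated counting -> coverage and
on-target statistics.

Bisulfite chemistry leaves methylated cytosines intact and converts
unmethylated cytosines to uracil (sequenced as T).  PCR of the converted
molecules yields four distinguishable sequence frames per amplicon, built
here from the top-strand reference S:

======  =======================  ==================  =====================
frame   reference sequence       read reduction      CpG call (raw base)
======  =======================  ==================  =====================
OT      S with C->T everywhere   C->T                C meth / T unmeth
CTOT    revcomp(OT)              G->A                G meth / A unmeth
OB      S with G->A everywhere   G->A                G meth / A unmeth
CTOB    revcomp(OB)              C->T                C meth / T unmeth
======  =======================  ==================  =====================

The OT frame contains no C and the OB frame no G, so a read reduced in the
frame-appropriate direction matches its frame exactly when fully converted.
The interrogated CpG position is the cytosine at amplicon offset ``p`` for
OT/CTOT and the paired cytosine on the opposite strand (top offset ``p+1``)
for OB/CTOB.

Alignment is exhaustive ungapped sliding-window scoring against the (small,
fixed-length) amplicon panel rather than an indexed genome aligner: every
offset of every frame is scored and a read is assigned to the unique best
hit when its match fraction reaches ``min_score_fraction`` (default 0.9);
ties are left unassigned as ambiguous.  Reads with indels fall below the
score floor and are dropped.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .io import Amplicon, FormatError, PanelDefinition

FRAMES = ("OT", "CTOT", "OB", "CTOB")
#: read-reduction direction required to match each frame
FRAME_REDUCTION = {"OT": "CT", "CTOT": "GA", "OB": "GA", "CTOB": "CT"}

_COMP = str.maketrans("ACGTN", "TGCAN")

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _onehot(enc: np.ndarray) -> np.ndarray:
    oh = np.zeros((enc.size, 4), dtype=np.float32)
    valid = enc < 4
    oh[np.nonzero(valid)[0], enc[valid]] = 1.0
    return oh


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a (possibly gzipped) FASTQ into (name, seq, qual) tuples."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(t.split()[0], s, q) for t, s, q in FastqGeneralIterator(fh)]


def write_fastq(records, path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------


def find_adapter_start(
    seq: str,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
) -> int | None:
    """Leftmost start of a 3' adapter occurrence, or ``None``.

    Semi-global: an internal occurrence must match the whole adapter; at the
    read's 3' end a prefix of the adapter of length >= ``min_overlap`` may
    match, with at most ``floor(rate * overlap)`` mismatches either way.
    """
    n, la = len(seq), len(adapter)
    if n < min_overlap or la == 0:
        return None
    enc_s = _encode(seq)
    enc_a = _encode(adapter)
    best = None
    n_full = n - la + 1
    if n_full > 0:
        windows = np.lib.stride_tricks.sliding_window_view(enc_s, la)
        mism = (windows != enc_a).sum(axis=1)
        ok = np.nonzero(mism <= int(max_mismatch_rate * la))[0]
        if ok.size:
            best = int(ok[0])
    # 3' tail: partial-overlap starts
    tail_from = max(n_full, 0)
    limit = n - min_overlap + 1
    for i in range(tail_from, limit):
        if best is not None and best <= i:
            break
        ov = n - i
        mism = int((enc_s[i:] != enc_a[:ov]).sum())
        if mism <= int(max_mismatch_rate * ov):
            return i
    return best


def trim_read(
    seq: str,
    qual: str,
    adapters,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
) -> tuple[str, str]:
    cut = len(seq)
    for adapter in adapters:
        hit = find_adapter_start(seq, adapter, min_overlap, max_mismatch_rate)
        if hit is not None and hit < cut:
            cut = hit
    return seq[:cut], qual[:cut]


def trim_adapters(
    records1,
    records2,
    adapters,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    min_length: int = 30,
):
    """Trim 3' adapters from paired records; drop short pairs together.

    ``records1``/``records2`` are record-aligned lists of (name, seq, qual);
    a pair is dropped when either trimmed mate is shorter than
    ``min_length``.  Returns (trimmed1, trimmed2, n_pairs_dropped).
    """
    if len(records1) != len(records2):
        raise FormatError(
            f"unpaired FASTQ inputs: {len(records1)} vs {len(records2)} records"
        )
    out1, out2, dropped = [], [], 0
    for (n1, s1, q1), (n2, s2, q2) in zip(records1, records2):
        if n1 != n2:
            raise FormatError(f"mate names differ: {n1!r} vs {n2!r}")
        t1, tq1 = trim_read(s1, q1, adapters, min_overlap, max_mismatch_rate)
        t2, tq2 = trim_read(s2, q2, adapters, min_overlap, max_mismatch_rate)
        if len(t1) < min_length or len(t2) < min_length:
            dropped += 1
            continue
        out1.append((n1, t1, tq1))
        out2.append((n2, t2, tq2))
    return out1, out2, dropped


# ---------------------------------------------------------------------------
# bisulfite reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGSite:
    locus_id: str
    frame_offset: int
    meth_base: str
    unmeth_base: str


@dataclass(frozen=True)
class ConversionSite:
    """A non-CpG cytosine interrogation point (conversion-efficiency QC)."""

    frame_offset: int
    converted_base: str
    unconverted_base: str


@dataclass
class BisulfiteReferenceSet:
    """Four converted frames per amplicon plus per-frame CpG position maps."""

    frames: dict[tuple[str, str], str]  # (amplicon_id, frame) -> sequence
    cpg_sites: dict[tuple[str, str], list[CpGSite]]
    conversion_sites: dict[tuple[str, str], list[ConversionSite]]

    def amplicon_ids(self) -> list[str]:
        return sorted({a for a, _ in self.frames})


def _in_spans(pos: int, spans) -> bool:
    return any(s <= pos < e for s, e in spans)


def build_bisulfite_reference(panel: PanelDefinition) -> BisulfiteReferenceSet:
    """In-silico bisulfite conversion of every amplicon into four frames.

    Raises on ambiguity codes other than N.  CpG interrogation positions
    that fall inside primer spans are excluded from the maps (primer bases
    are synthetic and carry no methylation signal).
    """
    frames: dict[tuple[str, str], str] = {}
    cpg_sites: dict[tuple[str, str], list[CpGSite]] = {}
    conv_sites: dict[tuple[str, str], list[ConversionSite]] = {}
    for amp in panel.amplicons.values():
        s = amp.sequence.upper()
        if set(s) - set("ACGTN"):
            raise ValueError(
                f"amplicon {amp.amplicon_id} contains ambiguity codes other than N"
            )
        n = len(s)
        ot = s.replace("C", "T")
        ob = s.replace("G", "A")
        frames[(amp.amplicon_id, "OT")] = ot
        frames[(amp.amplicon_id, "CTOT")] = revcomp(ot)
        frames[(amp.amplicon_id, "OB")] = ob
        frames[(amp.amplicon_id, "CTOB")] = revcomp(ob)
        for fr in FRAMES:
            cpg_sites[(amp.amplicon_id, fr)] = []
            conv_sites[(amp.amplicon_id, fr)] = []
        for loc in panel.loci_of(amp.amplicon_id):
            p = loc.cpg_offset
            if not _in_spans(p, amp.primer_spans):
                cpg_sites[(amp.amplicon_id, "OT")].append(
                    CpGSite(loc.locus_id, p, "C", "T")
                )
                cpg_sites[(amp.amplicon_id, "CTOT")].append(
                    CpGSite(loc.locus_id, n - 1 - p, "G", "A")
                )
            if not _in_spans(p + 1, amp.primer_spans):
                cpg_sites[(amp.amplicon_id, "OB")].append(
                    CpGSite(loc.locus_id, p + 1, "G", "A")
                )
                cpg_sites[(amp.amplicon_id, "CTOB")].append(
                    CpGSite(loc.locus_id, n - 2 - p, "C", "T")
                )
        target_offsets = {loc.cpg_offset for loc in panel.loci_of(amp.amplicon_id)}
        for j, base in enumerate(s):
            if _in_spans(j, amp.primer_spans):
                continue
            if base == "C" and (j + 1 >= n or s[j + 1] != "G"):
                conv_sites[(amp.amplicon_id, "OT")].append(
                    ConversionSite(j, "T", "C")
                )
                conv_sites[(amp.amplicon_id, "CTOT")].append(
                    ConversionSite(n - 1 - j, "A", "G")
                )
            if base == "G" and (j == 0 or s[j - 1] != "C"):
                conv_sites[(amp.amplicon_id, "OB")].append(
                    ConversionSite(j, "A", "G")
                )
                conv_sites[(amp.amplicon_id, "CTOB")].append(
                    ConversionSite(n - 1 - j, "T", "C")
                )
        # non-target CpG cytosines are neither CpG sites nor QC sites
        del target_offsets
    return BisulfiteReferenceSet(frames, cpg_sites, conv_sites)


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentSet:
    """Per-read best-hit table plus the original (unreduced) sequences.

    ``table`` columns: name, mate, length, amplicon_id, frame, offset,
    matches, score, status (assigned / unassigned / ambiguous).  Row *i*
    describes ``sequences[i]``.
    """

    table: pd.DataFrame
    sequences: list[str]
    amplicon_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "assigned"]


def paired_records(records1, records2):
    """Flatten paired (name, seq, qual) lists into (name, mate, seq) reads."""
    reads = [(n, 1, s) for n, s, _ in records1]
    reads += [(n, 2, s) for n, s, _ in records2]
    return reads


def assign_reads(
    reads,
    ref: BisulfiteReferenceSet,
    min_score_fraction: float = 0.9,
    chunk_size: int = 2048,
) -> AlignmentSet:
    """Assign each read to its best (amplicon, frame, offset) by exhaustive
    ungapped scoring, after frame-appropriate bisulfite reduction.

    ``reads`` is an iterable of (name, mate, sequence).  A read is assigned
    when the unique best window matches >= ``min_score_fraction`` of its
    bases; equal-best windows leave the read ambiguous.
    """
    reads = list(reads)
    names = [r[0] for r in reads]
    mates = [int(r[1]) for r in reads]
    seqs = [r[2].upper() for r in reads]
    n_reads = len(reads)

    result = {
        "amplicon_id": [None] * n_reads,
        "frame": [None] * n_reads,
        "offset": np.full(n_reads, -1, dtype=int),
        "matches": np.zeros(n_reads, dtype=int),
        "status": ["unassigned"] * n_reads,
    }

    frame_enc = {key: _encode(s) for key, s in ref.frames.items()}

    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)

    for length, idxs in by_len.items():
        if length == 0:
            continue
        win_blocks, meta = [], []
        for (amp, fr), enc in frame_enc.items():
            if enc.size < length:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc, length)
            red = FRAME_REDUCTION[fr]
            win_blocks.append((red, windows))
            for off in range(windows.shape[0]):
                meta.append((amp, fr, off, red))
        if not win_blocks:
            continue
        # one-hot window matrices per reduction direction
        w_parts = {"CT": [], "GA": []}
        m_parts = {"CT": [], "GA": []}
        pos = 0
        for red, windows in win_blocks:
            oh = _onehot(windows.reshape(-1)).reshape(windows.shape[0], length * 4)
            w_parts[red].append(oh)
            m_parts[red].append(meta[pos : pos + windows.shape[0]])
            pos += windows.shape[0]
        mats, metas = {}, {}
        for red in ("CT", "GA"):
            if w_parts[red]:
                mats[red] = np.concatenate(w_parts[red], axis=0)
                metas[red] = [m for part in m_parts[red] for m in part]

        min_matches = min_score_fraction * length - 1e-9
        for start in range(0, len(idxs), chunk_size):
            batch = idxs[start : start + chunk_size]
            enc_batch = np.stack([_encode(seqs[i]) for i in batch])
            scores_cols, col_meta = [], []
            for red in ("CT", "GA"):
                if red not in mats:
                    continue
                reduced = enc_batch.copy()
                if red == "CT":
                    reduced[reduced == 1] = 3  # C -> T
                else:
                    reduced[reduced == 2] = 0  # G -> A
                oh = _onehot(reduced.reshape(-1)).reshape(len(batch), length * 4)
                scores_cols.append(oh @ mats[red].T)
                col_meta.extend(metas[red])
            scores = np.concatenate(scores_cols, axis=1)
            best_col = np.argmax(scores, axis=1)
            best_val = scores[np.arange(len(batch)), best_col]
            n_best = (scores >= best_val[:, None] - 0.5).sum(axis=1)
            for k, i in enumerate(batch):
                m = int(round(best_val[k]))
                if m < min_matches:
                    continue
                if n_best[k] > 1:
                    result["status"][i] = "ambiguous"
                    continue
                amp, fr, off, _ = col_meta[int(best_col[k])]
                result["amplicon_id"][i] = amp
                result["frame"][i] = fr
                result["offset"][i] = off
                result["matches"][i] = m
                result["status"][i] = "assigned"

    lengths = np.array([len(s) for s in seqs], dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(lengths > 0, result["matches"] / np.maximum(lengths, 1), 0.0)
    table = pd.DataFrame(
        {
            "name": names,
            "mate": mates,
            "length": lengths,
            "amplicon_id": result["amplicon_id"],
            "frame": result["frame"],
            "offset": result["offset"],
            "matches": result["matches"],
            "score": score,
            "status": result["status"],
        }
    )
    amp_lengths = {a: len(next(s for (aa, f), s in ref.frames.items() if aa == a))
                   for a in ref.amplicon_ids()}
    return AlignmentSet(table=table, sequences=seqs, amplicon_lengths=amp_lengths)


# ---------------------------------------------------------------------------
# methylation extraction
# ---------------------------------------------------------------------------


@dataclass
class MethylationCallSet:
    """Per-locus methylated/unmethylated read counts for one sample.

    ``table`` is indexed by locus id with columns n_meth, n_unmeth,
    coverage and beta; loci under the coverage floor carry a missing beta
    (NaN), never 0.  ``conversion_rate`` is the per-sample bisulfite
    conversion efficiency estimated from non-CpG cytosines (reported, not
    used to correct betas).
    """

    table: pd.DataFrame
    conversion_rate: float | None = None
    min_coverage: int = 10

    def beta_series(self, name: str = "sample") -> pd.Series:
        return self.table["beta"].rename(name)


def extract_methylation(
    alignments: AlignmentSet,
    panel: PanelDefinition,
    ref: BisulfiteReferenceSet,
    min_coverage: int = 10,
) -> MethylationCallSet:
    """Count methylated/unmethylated read bases at every target CpG.

    Raw (unreduced) read bases are consulted at each mapped CpG position;
    bases other than the frame's meth/unmeth pair are ignored.  Paired
    mates covering the same CpG of the same fragment are counted once
    (mate 1 wins).
    """
    panel_ids = set(panel.locus_ids)
    for sites in ref.cpg_sites.values():
        for site in sites:
            if site.locus_id not in panel_ids:
                raise KeyError(f"locus {site.locus_id} absent from panel")

    # (fragment, locus) -> (mate, is_methylated)
    calls: dict[tuple[str, str], tuple[int, bool]] = {}
    conv_converted = 0
    conv_unconverted = 0

    tab = alignments.assigned
    for row, seq in zip(tab.itertuples(), (alignments.sequences[i] for i in tab.index)):
        key = (row.amplicon_id, row.frame)
        off, ln = row.offset, len(seq)
        for site in ref.cpg_sites.get(key, ()):
            rel = site.frame_offset - off
            if 0 <= rel < ln:
                base = seq[rel]
                if base == site.meth_base:
                    meth = True
                elif base == site.unmeth_base:
                    meth = False
                else:
                    continue
                ck = (row.name, site.locus_id)
                prev = calls.get(ck)
                if prev is None or row.mate < prev[0]:
                    calls[ck] = (row.mate, meth)
        for site in ref.conversion_sites.get(key, ()):
            rel = site.frame_offset - off
            if 0 <= rel < ln:
                base = seq[rel]
                if base == site.converted_base:
                    conv_converted += 1
                elif base == site.unconverted_base:
                    conv_unconverted += 1

    n_meth = {lid: 0 for lid in panel.locus_ids}
    n_unmeth = {lid: 0 for lid in panel.locus_ids}
    for (_, lid), (_, meth) in calls.items():
        if meth:
            n_meth[lid] += 1
        else:
            n_unmeth[lid] += 1

    rows = []
    for lid in panel.locus_ids:
        cov = n_meth[lid] + n_unmeth[lid]
        beta = n_meth[lid] / cov if cov >= min_coverage else np.nan
        rows.append((lid, n_meth[lid], n_unmeth[lid], cov, beta))
    table = pd.DataFrame(
        rows, columns=["locus_id", "n_meth", "n_unmeth", "coverage", "beta"]
    ).set_index("locus_id")

    denom = conv_converted + conv_unconverted
    conversion = conv_converted / denom if denom else None
    return MethylationCallSet(table, conversion_rate=conversion, min_coverage=min_coverage)


def write_call_set(call_set: MethylationCallSet, path) -> None:
    call_set.table.to_csv(path, sep="\t", na_rep="NA", index_label="locus_id")


def read_call_set(path, min_coverage: int = 10) -> MethylationCallSet:
    table = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return MethylationCallSet(table, min_coverage=min_coverage)


# ---------------------------------------------------------------------------
# coverage statistics
# ---------------------------------------------------------------------------


@dataclass
class CoverageReport:
    total_reads: int
    aligned_reads: int
    on_target_fraction: float | None
    mean_depth: float | None
    per_amplicon: pd.DataFrame  # index amplicon_id: n_fragments, bases, depth
    depth_range: tuple[float, float] | None

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "total_reads": self.total_reads,
                "aligned_reads": self.aligned_reads,
                "on_target_fraction": self.on_target_fraction,
                "mean_depth": self.mean_depth,
                "min_depth": None if self.depth_range is None else self.depth_range[0],
                "max_depth": None if self.depth_range is None else self.depth_range[1],
            }
        )


def _top_interval(frame: str, offset: int, read_len: int, amp_len: int):
    """Map a frame-coordinate placement to a top-strand interval."""
    if frame in ("OT", "OB"):
        return offset, offset + read_len
    return amp_len - offset - read_len, amp_len - offset


def coverage_stats(alignments: AlignmentSet, panel: PanelDefinition) -> CoverageReport:
    """On-target fraction and fold depth per amplicon.

    Depth counts each sequenced fragment once: mate intervals are unioned
    in top-strand coordinates, so an overlapping pair does not double-count
    its overlap.  on_target_fraction = assigned reads / total reads (the
    panel-only aligner has no off-target reference to align to).
    """
    total = len(alignments.table)
    tab = alignments.assigned
    aligned = len(tab)
    frag_intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in tab.itertuples():
        amp_len = alignments.amplicon_lengths[row.amplicon_id]
        iv = _top_interval(row.frame, row.offset, row.length, amp_len)
        frag_intervals.setdefault((row.name, row.amplicon_id), []).append(iv)

    bases: dict[str, int] = {a: 0 for a in panel.amplicons}
    fragments: dict[str, int] = {a: 0 for a in panel.amplicons}
    for (_, amp), ivs in frag_intervals.items():
        ivs.sort()
        covered, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
        if cur_s is not None:
            covered += cur_e - cur_s
        bases[amp] = bases.get(amp, 0) + covered
        fragments[amp] = fragments.get(amp, 0) + 1

    rows = []
    for amp_id, amp in panel.amplicons.items():
        depth = bases[amp_id] / len(amp.sequence)
        rows.append((amp_id, fragments[amp_id], bases[amp_id], depth))
    per_amp = pd.DataFrame(
        rows, columns=["amplicon_id", "n_fragments", "bases", "depth"]
    ).set_index("amplicon_id")

    total_len = sum(len(a.sequence) for a in panel.amplicons.values())
    mean_depth = per_amp["bases"].sum() / total_len if total_len else None
    depth_range = (
        (float(per_amp["depth"].min()), float(per_amp["depth"].max()))
        if len(per_amp)
        else None
    )
    return CoverageReport(
        total_reads=total,
        aligned_reads=aligned,
        on_target_fraction=(aligned / total) if total else None,
        mean_depth=mean_depth,
        per_amplicon=per_amp,
        depth_range=depth_range,
    )
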