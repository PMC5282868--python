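"""Synthetic cohorts, urine mixtures, amplicon panels and bisulfite reads.

Every generator is fully deterministic under its seed and emits its ground
truth alongside the data, so downstream tests consume truth rather than
re-deriving it.

The cohort generator emulates the statistical structure of a marker
discovery study: marker loci are unmethylated (beta below a hard margin) in
every non-cancer tissue class and methylated in a majority of cancers, with
inter-tumour heterogeneity (a per-locus penetrance drawn from a stated
interval decides which cancers are methylated) and a low-grade tumour
stratum retaining a stated fraction (default 98%) of the high-grade
methylation alterations.  Beta-distributed noise models array-like beta
values.  With ``enforce_filter_margin`` (the default) each marker's
methylated-cancer count is clamped to a strict majority and noise is
truncated at the margins, so the discovery filter recovers the planted set
by construction; switching it off gives free Binomial penetrance draws for
heterogeneous-cohort experiments.

Urine sediment is modelled as a two-component cell mixture: case profiles
are ``w * tumour + (1 - w) * normal`` plus noise, controls are normal
profiles plus noise; ``w`` is the tumour-cell fraction of the sediment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsquant import FRAMES, _ENC, _encode
from .io import Amplicon, BetaMatrix, PanelDefinition, SampleSheet, TargetLocus

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N


def _decode_rows(arr: np.ndarray) -> list[str]:
    mapped = _DECODE[arr]
    return [row.tobytes().decode("ascii") for row in mapped]


def _trunc_beta(rng, a, b, size, low=0.0, high=1.0) -> np.ndarray:
    """Beta(a, b) draws rejected outside [low, high]."""
    out = rng.beta(a, b, size=size)
    for _ in range(1000):
        bad = (out < low) | (out > high)
        if not bad.any():
            return out
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
    raise RuntimeError("truncated beta sampling did not converge")


# ---------------------------------------------------------------------------
# methylome cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study-cohort structure for the synthetic methylome generator.

    Sample counts default to the discovery-cohort layout (86 cancers, 30
    normal urothelium, plus blood and non-cancer urine reference samples);
    ``penetrance_range`` is the interval the per-locus fraction of
    methylated cancers is drawn from; ``meth_beta``/``unmeth_beta`` are the
    Beta-noise shape pairs for methylated (mean ~0.75) and unmethylated
    (mean ~0.03) states, or ``None`` for noise-free constants.
    """

    n_cancer: int = 86
    n_normal: int = 30
    n_blood: int = 20
    n_noncancer_urine: int = 10
    n_loci_background: int = 2000
    n_loci_marker: int = 150
    penetrance_range: tuple[float, float] = (0.5, 1.0)
    meth_beta: tuple[float, float] | None = (6.0, 2.0)
    unmeth_beta: tuple[float, float] | None = (1.5, 48.5)
    meth_min: float = 0.55
    unmeth_max: float = 0.08
    meth_value: float = 0.75  # used when meth_beta is None
    unmeth_value: float = 0.02  # used when unmeth_beta is None
    low_grade_fraction: float = 0.0
    low_grade_marker_retention: float = 0.98
    enforce_filter_margin: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer", "n_normal", "n_blood", "n_noncancer_urine",
                     "n_loci_background", "n_loci_marker"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.penetrance_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("penetrance_range must lie in [0, 1]")
        for name in ("low_grade_fraction", "low_grade_marker_retention"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Generator ground truth: the planted marker set and per-sample
    per-locus methylated states (before and after low-grade thinning)."""

    marker_loci: list[str]
    penetrance: pd.Series
    meth_states: pd.DataFrame  # marker loci x cancer samples, bool
    base_meth_states: pd.DataFrame  # before low-grade retention thinning
    low_grade_samples: list[str]


def _draw_state_values(rng, spec: CohortSpec, meth_mask: np.ndarray) -> np.ndarray:
    """Fill a beta array from the methylated/unmethylated noise models."""
    out = np.empty(meth_mask.shape, dtype=float)
    n_meth = int(meth_mask.sum())
    n_unmeth = meth_mask.size - n_meth
    if spec.meth_beta is None:
        out[meth_mask] = spec.meth_value
    else:
        out[meth_mask] = _trunc_beta(
            rng, *spec.meth_beta, n_meth, low=spec.meth_min
        )
    if spec.unmeth_beta is None:
        out[~meth_mask] = spec.unmeth_value
    else:
        out[~meth_mask] = _trunc_beta(
            rng, *spec.unmeth_beta, n_unmeth, high=spec.unmeth_max
        )
    return out


def simulate_cohort(spec: CohortSpec):
    """Generate (BetaMatrix, SampleSheet, CohortTruth) for one cohort."""
    n_loci = spec.n_loci_marker + spec.n_loci_background
    if n_loci == 0:
        raise ValueError("cohort must contain at least one locus")
    rng = np.random.default_rng(spec.seed)

    cancer_ids = [f"ca{i + 1:03d}" for i in range(spec.n_cancer)]
    normal_ids = [f"nu{i + 1:03d}" for i in range(spec.n_normal)]
    blood_ids = [f"bl{i + 1:03d}" for i in range(spec.n_blood)]
    urine_ids = [f"ncu{i + 1:03d}" for i in range(spec.n_noncancer_urine)]
    samples = cancer_ids + normal_ids + blood_ids + urine_ids

    n_low = int(round(spec.low_grade_fraction * spec.n_cancer))
    low_idx = rng.choice(spec.n_cancer, size=n_low, replace=False) if n_low else np.array([], int)
    low_set = {cancer_ids[i] for i in low_idx}

    sheet_rows = []
    for s in cancer_ids:
        low = s in low_set
        sheet_rows.append((s, "cancer", "Ta-T1" if low else "T2-T4",
                           "low" if low else "high"))
    for s in normal_ids:
        sheet_rows.append((s, "normal_urothelium", None, None))
    for s in blood_ids:
        sheet_rows.append((s, "blood", None, None))
    for s in urine_ids:
        sheet_rows.append((s, "noncancer_urine", None, None))
    sheet = SampleSheet(
        pd.DataFrame(
            sheet_rows, columns=["sample_id", "group", "stage", "grade"]
        ).set_index("sample_id")
    )

    marker_ids = [f"mk{i + 1:05d}" for i in range(spec.n_loci_marker)]
    bg_ids = [f"bg{i + 1:05d}" for i in range(spec.n_loci_background)]
    locus_ids = marker_ids + bg_ids

    # planted marker structure
    penetrance = rng.uniform(*spec.penetrance_range, size=spec.n_loci_marker)
    base_states = np.zeros((spec.n_loci_marker, spec.n_cancer), dtype=bool)
    for i, p in enumerate(penetrance):
        if spec.enforce_filter_margin and spec.n_cancer:
            n_meth = int(round(p * spec.n_cancer))
            n_meth = int(np.clip(n_meth, spec.n_cancer // 2 + 1, spec.n_cancer))
            cols = rng.choice(spec.n_cancer, size=n_meth, replace=False)
            base_states[i, cols] = True
        else:
            base_states[i] = rng.random(spec.n_cancer) < p
    states = base_states.copy()
    if n_low and spec.low_grade_marker_retention < 1.0:
        retain = rng.random((spec.n_loci_marker, n_low)) < spec.low_grade_marker_retention
        states[:, low_idx] &= retain

    values = np.empty((n_loci, len(samples)), dtype=float)
    if spec.n_loci_marker:
        values[: spec.n_loci_marker, : spec.n_cancer] = _draw_state_values(
            rng, spec, states
        )
        n_noncancer = len(samples) - spec.n_cancer
        values[: spec.n_loci_marker, spec.n_cancer :] = _draw_state_values(
            rng, spec, np.zeros((spec.n_loci_marker, n_noncancer), dtype=bool)
        )
    if spec.n_loci_background:
        baseline = rng.uniform(0.0, 1.0, size=spec.n_loci_background)
        a = 1.0 + 8.0 * baseline
        b = 1.0 + 8.0 * (1.0 - baseline)
        values[spec.n_loci_marker :, :] = rng.beta(
            a[:, None], b[:, None], size=(spec.n_loci_background, len(samples))
        )

    coords = pd.DataFrame(
        {
            "chromosome": [f"chr{(i % 22) + 1}" for i in range(n_loci)],
            "position": [1_000_000 + 1_000 * i for i in range(n_loci)],
            "strand": "+",
        },
        index=locus_ids,
    )
    betas = BetaMatrix(pd.DataFrame(values, index=locus_ids, columns=samples), coords)
    truth = CohortTruth(
        marker_loci=marker_ids,
        penetrance=pd.Series(penetrance, index=marker_ids, name="penetrance"),
        meth_states=pd.DataFrame(states, index=marker_ids, columns=cancer_ids),
        base_meth_states=pd.DataFrame(base_states, index=marker_ids, columns=cancer_ids),
        low_grade_samples=sorted(low_set),
    )
    return betas, sheet, truth


# ---------------------------------------------------------------------------
# urine sediment mixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UrineSpec:
    """Urine-sediment cohort: per-case tumour-cell fraction ``w`` (a float,
    an interval to draw from, or a per-case sequence) plus Gaussian
    measurement noise."""

    n_cases: int = 30
    n_controls: int = 30
    tumour_cell_fraction: float | tuple[float, float] = 0.7
    noise_sd: float = 0.02
    seed: int = 0


def simulate_urine(betas: BetaMatrix, sheet: SampleSheet, spec: UrineSpec):
    """Mix tumour and normal methylome profiles into urine-sediment samples.

    Returns (BetaMatrix, SampleSheet, truth labels, mixture weights).
    """
    rng = np.random.default_rng(spec.seed)
    cancer_cols = sheet.samples_in("cancer")
    normal_cols = sheet.samples_in("normal_urothelium")
    if not cancer_cols or not normal_cols:
        raise ValueError("urine simulation needs cancer and normal profiles")

    w = spec.tumour_cell_fraction
    if isinstance(w, (tuple, list)) and len(w) == 2 and np.isscalar(w[0]):
        weights = rng.uniform(w[0], w[1], size=spec.n_cases)
    elif np.isscalar(w):
        weights = np.full(spec.n_cases, float(w))
    else:
        weights = np.asarray(w, dtype=float)
        if weights.size != spec.n_cases:
            raise ValueError("per-case weights must match n_cases")
    if ((weights < 0) | (weights > 1)).any():
        raise ValueError("tumour cell fractions must lie in [0, 1]")

    vals = betas.values
    cols, labels, rows = [], {}, []
    out = np.empty((vals.shape[0], spec.n_cases + spec.n_controls))
    for i in range(spec.n_cases):
        t = vals[rng.choice(cancer_cols)].to_numpy()
        nprof = vals[rng.choice(normal_cols)].to_numpy()
        mixed = weights[i] * t + (1.0 - weights[i]) * nprof
        out[:, i] = mixed
        sid = f"uc{i + 1:03d}"
        cols.append(sid)
        labels[sid] = 1
        rows.append((sid, "urine_case"))
    for i in range(spec.n_controls):
        nprof = vals[rng.choice(normal_cols)].to_numpy()
        out[:, spec.n_cases + i] = nprof
        sid = f"unc{i + 1:03d}"
        cols.append(sid)
        labels[sid] = 0
        rows.append((sid, "noncancer_urine"))
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    out = np.clip(out, 0.0, 1.0)

    urine_betas = BetaMatrix(
        pd.DataFrame(out, index=vals.index, columns=cols), betas.coords
    )
    urine_sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "group"]).set_index("sample_id")
    )
    return (
        urine_betas,
        urine_sheet,
        pd.Series(labels, name="truth"),
        pd.Series(weights, index=cols[: spec.n_cases], name="tumour_cell_fraction"),
    )


# ---------------------------------------------------------------------------
# amplicon panels
# ---------------------------------------------------------------------------


def simulate_panel(
    marker_loci,
    coords: pd.DataFrame | None = None,
    seed: int = 0,
    primer_length: int = 20,
    length_range: tuple[int, int] = (120, 300),
) -> PanelDefinition:
    """Random amplicon panel with one planted target CpG per marker locus.

    Amplicon lengths are drawn from the PCR fragment range (default
    120-300 bp); primers occupy ``primer_length`` bases at each end and the
    CpG is planted strictly between them.
    """
    rng = np.random.default_rng(seed)
    loci, amplicons = [], {}
    for i, lid in enumerate(marker_loci):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = rng.integers(0, 4, size=n)
        offset = int(rng.integers(primer_length + 5, n - primer_length - 6))
        seq[offset] = 1  # C
        seq[offset + 1] = 2  # G
        sequence = _decode_rows(seq[None, :].astype(np.uint8))[0]
        if coords is not None and lid in coords.index:
            chrom = coords.at[lid, "chromosome"]
            position = int(coords.at[lid, "position"])
        else:
            chrom = f"chr{(i % 22) + 1}"
            position = 1_000_000 + 1_000 * i
        if position - offset < 1:
            position = offset + 1
        amp_id = f"amp_{lid}"
        amplicons[amp_id] = Amplicon(
            amplicon_id=amp_id,
            sequence=sequence,
            chromosome=chrom,
            start=position - offset,
            primer_spans=((0, primer_length), (n - primer_length, n)),
        )
        loci.append(
            TargetLocus(
                locus_id=lid,
                chromosome=chrom,
                position=position,
                amplicon_id=amp_id,
                cpg_offset=offset,
            )
        )
    return PanelDefinition(loci=loci, amplicons=amplicons)


# ---------------------------------------------------------------------------
# bisulfite amplicon reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimSpec:
    """Sequencing-run model for the amplicon read simulator.

    Per-amplicon fold coverage is drawn around ``mean_coverage`` (Gamma,
    shape 4) and clipped to ``coverage_range``; defaults reflect a deep
    targeted run (mean 1254-fold, range 123-2673).  Unmethylated cytosines
    convert with probability ``conversion_rate``; substitution errors occur
    per base at ``error_rate``; the four bisulfite strand frames are
    emitted in equal proportion.
    """

    mean_coverage: float = 1254.0
    coverage_range: tuple[int, int] = (123, 2673)
    read_length: int = 150
    conversion_rate: float = 0.995
    error_rate: float = 0.003
    off_target_fraction: float = 0.03
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    frames: tuple[str, ...] = FRAMES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "error_rate", "off_target_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(f not in FRAMES for f in self.frames):
            raise ValueError(f"frames must be among {FRAMES}")


@dataclass
class ReadTruth:
    """Per-fragment ground truth emitted with every simulated run."""

    fragments: pd.DataFrame  # index name: amplicon_id, frame, off_target
    meth_states: pd.DataFrame  # name x locus_id, boolean (NaN off-amplicon)

    def truth_counts(self) -> pd.DataFrame:
        """Expected per-locus methylated/unmethylated fragment counts."""
        n_meth = self.meth_states.sum(axis=0, skipna=True).astype(int)
        n_total = self.meth_states.notna().sum(axis=0)
        return pd.DataFrame(
            {"n_meth": n_meth, "n_unmeth": (n_total - n_meth).astype(int)}
        )


def _apply_errors(arr: np.ndarray, rate: float, rng) -> np.ndarray:
    mask = rng.random(arr.shape) < rate
    shift = rng.integers(1, 4, size=arr.shape)
    out = arr.copy()
    out[mask] = (out[mask] + shift[mask]) % 4
    return out


def simulate_reads(panel: PanelDefinition, beta_truth: pd.Series, spec: ReadSimSpec):
    """Simulate paired-end bisulfite amplicon reads with full ground truth.

    ``beta_truth`` maps each panel locus to its true methylation fraction;
    each fragment draws an independent methylated/unmethylated state per
    CpG.  Returns (records1, records2, ReadTruth) where records are
    (name, seq, qual) tuples.
    """
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    adapter_enc = _encode(spec.adapter)

    frag_rows = []  # (name, amplicon, frame, off_target)
    meth_rows: dict[str, dict[str, bool]] = {}
    recs1, recs2 = [], []
    counter = 0

    for amp_id, amp in panel.amplicons.items():
        s_enc = _encode(amp.sequence)
        n = s_enc.size
        targets = panel.loci_of(amp_id)
        t_offsets = np.array([t.cpg_offset for t in targets], dtype=int)
        t_betas = np.array(
            [np.nan_to_num(float(beta_truth.get(t.locus_id, 0.0))) for t in targets]
        )
        c_pos = np.nonzero(s_enc == 1)[0]
        g_pos = np.nonzero(s_enc == 2)[0]

        depth = int(np.clip(rng.gamma(4.0, spec.mean_coverage / 4.0),
                            spec.coverage_range[0], spec.coverage_range[1]))
        frame_idx = rng.integers(0, len(spec.frames), size=depth)
        meth = rng.random((depth, t_offsets.size)) < t_betas[None, :]
        conv_c = rng.random((depth, c_pos.size)) < spec.conversion_rate
        conv_g = rng.random((depth, g_pos.size)) < spec.conversion_rate

        top_rows = np.array(
            [spec.frames[k] in ("OT", "CTOT") for k in frame_idx]
        )
        tmpl = np.tile(s_enc, (depth, 1))
        # top strands: unmethylated / non-CpG C -> T
        if c_pos.size:
            sub = tmpl[top_rows][:, c_pos]
            sub[conv_c[top_rows]] = 3
            tmpl[np.ix_(top_rows, c_pos)] = sub
        # bottom strands: G -> A (the converted bottom-strand C, top view)
        if g_pos.size:
            sub = tmpl[~top_rows][:, g_pos]
            sub[conv_g[~top_rows]] = 0
            tmpl[np.ix_(~top_rows, g_pos)] = sub
        # restore methylated target CpGs
        for j, off in enumerate(t_offsets):
            m = meth[:, j]
            tmpl[m & top_rows, off] = 1  # C retained on top strands
            tmpl[m & ~top_rows, off + 1] = 2  # G retained on bottom view

        # frame orientation: CTOT/CTOB templates are reverse complements
        rc_needed = np.array(
            [spec.frames[k] in ("CTOT", "CTOB") for k in frame_idx]
        )
        if rc_needed.any():
            tmpl[rc_needed] = _COMP_CODE[tmpl[rc_needed][:, ::-1]]

        # paired reads; adapter read-through when the template is short
        if n < rl:
            tail = np.concatenate([adapter_enc, rng.integers(0, 4, size=rl)])[: rl - n]
            pad = np.tile(tail, (depth, 1))
            fwd = np.concatenate([tmpl, pad], axis=1)
            rc_tmpl = _COMP_CODE[tmpl[:, ::-1]]
            rev = np.concatenate([rc_tmpl, pad], axis=1)
        else:
            fwd = tmpl
            rev = _COMP_CODE[tmpl[:, ::-1]]
        r1 = _apply_errors(fwd[:, :rl].astype(np.uint8), spec.error_rate, rng)
        r2 = _apply_errors(rev[:, :rl].astype(np.uint8), spec.error_rate, rng)

        seqs1 = _decode_rows(r1)
        seqs2 = _decode_rows(r2)
        qual = "I" * rl
        for i in range(depth):
            name = f"frag{counter:07d}"
            counter += 1
            recs1.append((name, seqs1[i], qual))
            recs2.append((name, seqs2[i], qual))
            frag_rows.append((name, amp_id, spec.frames[frame_idx[i]], False))
            meth_rows[name] = {
                targets[j].locus_id: bool(meth[i, j]) for j in range(len(targets))
            }

    # off-target reads: random sequence pairs
    n_on = len(recs1)
    f = spec.off_target_fraction
    n_off = int(round(n_on * f / (1.0 - f))) if f < 1.0 else 0
    for i in range(n_off):
        name = f"offt{i:07d}"
        s1 = _decode_rows(rng.integers(0, 4, size=(1, rl)).astype(np.uint8))[0]
        s2 = _decode_rows(rng.integers(0, 4, size=(1, rl)).astype(np.uint8))[0]
        recs1.append((name, s1, "I" * rl))
        recs2.append((name, s2, "I" * rl))
        frag_rows.append((name, None, None, True))

    perm = rng.permutation(len(recs1))
    recs1 = [recs1[i] for i in perm]
    recs2 = [recs2[i] for i in perm]

    fragments = pd.DataFrame(
        frag_rows, columns=["name", "amplicon_id", "frame", "off_target"]
    ).set_index("name")
    meth_states = pd.DataFrame.from_dict(meth_rows, orient="index").reindex(
        columns=panel.locus_ids
    )
    return recs1, recs2, ReadTruth(fragments=fragments, meth_states=meth_states)
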