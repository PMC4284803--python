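"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the study design end to end: a small genome with
a mixed-biotype annotation, treated/untreated binding-peak sets in which
planted direct-target genes carry a dimeric p53 response element
written into the genome sequence near their TSS, two replicate
differential-expression tables with planted significant transcripts,
active-chromatin mark tracks covering a configured fraction of genuine
5' ends (and never the planted artefact transcripts), and a paired
tumour/normal qPCR cohort in which signature markers are shifted toward
higher ΔCt (lower expression) in tumours.

All randomness flows from one seed, split into named substreams so each
stage regenerates independently and every file is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import (
    Biotype,
    GenomicInterval,
    TranscriptModel,
    write_annotation,
)

P53RE_CONSENSUS = "GGGCATGTCC" * 2  # dimeric site, spacer 0, zero mismatches

DEFAULT_BIOTYPE_MIX = {
    Biotype.MRNA: 0.55,
    Biotype.LNC_INTERGENIC: 0.10,
    Biotype.LNC_ANTISENSE: 0.07,
    Biotype.PROCESSED_TRANSCRIPT: 0.04,
    Biotype.PSEUDOGENE: 0.06,
    Biotype.OTHER_NCRNA: 0.03,
    Biotype.UNASSIGNED: 0.15,
}

# Cohort defaults mirror the assayed panel: 12 markers of which 5 carry a
# strong tumour shift, 2 a moderate one and 5 none.
DEFAULT_MARKER_DELTAS = (2.5, 2.5, 2.5, 2.5, 2.5, 0.9, 0.9, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulationConfig:
    seed: int
    n_chromosomes: int = 2
    chromosome_length: int = 4_500_000
    n_genes: int = 300
    biotype_mix: Mapping[Biotype, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_MIX)
    )
    artefact_fraction: float = 0.4  # of unassigned transcripts
    n_planted_targets: int = 30
    site_offset_range: int = 8_000  # planted p53RE within ±range of the TSS
    peak_width: int = 400
    summit_jitter: int = 40
    n_decoy_peaks: int = 60
    decoy_proximal_fraction: float = 0.5  # decoys near a non-target TSS
    untreated_fraction: float = 0.4  # of treated peaks also present untreated
    orf_coverage: float = 0.6  # of spliced length, for planted mRNA ORFs
    de_alpha: float = 0.01
    de_null_lfc_sd: float = 0.2
    de_planted_lfc_mean: float = 2.0
    de_planted_lfc_sd: float = 0.5
    de_planted_beta_a: float = 0.01  # p ~ Beta(a, 1) for planted transcripts
    de_up_fraction: float = 0.75  # fraction of planted targets induced
    noiseless: bool = False
    mark_fraction: float = 0.9  # genuine 5' ends carrying ≥1 mark
    mark_width: int = 1_000
    mark_jitter: int = 2_000
    coverage_bump_height: float = 40.0
    coverage_bump_sd: float = 100.0
    coverage_noise: float = 1.0
    coverage_window: int = 3_000
    coverage_bin: int = 10
    n_patients: int = 35
    marker_deltas: Sequence[float] = DEFAULT_MARKER_DELTAS
    cohort_sigma: float = 1.0
    patient_sd: float = 0.5
    reference_ct: float = 20.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        total = sum(self.biotype_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"biotype mix sums to {total}, expected 1")
        if min(self.biotype_mix.values()) < 0 or self.n_genes < 0:
            raise ValueError("negative counts/fractions in configuration")


def _spawn(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the global seed: each stage regenerates
    independently of the others."""
    digest = np.frombuffer(stream.encode(), dtype=np.uint8).sum()
    return np.random.default_rng(np.random.SeedSequence((seed, int(digest))))


@dataclass
class TruthTable:
    genes: pd.DataFrame  # gene_id, biotype, chrom, tss, strand, is_direct_target, direction, planted_site_pos
    transcripts: pd.DataFrame  # transcript_id, gene_id, label (genuine|artefact), marked
    markers: pd.DataFrame  # marker, delta, mu

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="records"),
            "transcripts": self.transcripts.to_dict(orient="records"),
            "markers": self.markers.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


# --- genome + annotation ----------------------------------------------


def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], list[TranscriptModel], TruthTable]:
    """Random-uniform genome plus a non-overlapping gene annotation.

    Genes are laid out on evenly spaced slots; unassigned transcripts
    flagged as artefacts are re-positioned just downstream of a host
    mRNA's 3' end on the same strand (run-through geometry), carrying no
    marks later. Raises when the requested genes do not fit.
    """
    rng = _spawn(config.seed, "genome")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=config.chromosome_length)]
        for i in range(config.n_chromosomes)
    }
    chroms = list(genome)
    gene_span_max = 5_000
    margin = 10_000  # keeps planted sites and peaks inside the chromosome
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    slot_per_chrom = config.chromosome_length // per_chrom
    if slot_per_chrom < gene_span_max + 2 * margin + 1_000:
        raise ValueError(
            f"{config.n_genes} genes do not fit {config.n_chromosomes} "
            f"chromosomes of {config.chromosome_length} bp"
        )

    mix_items = sorted(config.biotype_mix.items(), key=lambda kv: kv[0].value)
    labels = [b for b, _ in mix_items]
    target_counts = _apportion(config.n_genes, [f for _, f in mix_items])
    biotypes: list[Biotype] = sum(
        ([b] * c for b, c in zip(labels, target_counts)), []
    )
    rng.shuffle(biotypes)  # type: ignore[arg-type]

    transcripts: list[TranscriptModel] = []
    gene_rows = []
    tx_rows = []
    mrna_hosts: list[TranscriptModel] = []
    artefact_candidates: list[int] = []
    for g in range(config.n_genes):
        chrom = chroms[g // per_chrom]
        lo = (g % per_chrom) * slot_per_chrom + margin
        hi = min((g % per_chrom + 1) * slot_per_chrom, config.chromosome_length) - margin
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(2_000, gene_span_max))
        start = int(rng.integers(lo, hi - span))
        biotype = biotypes[g]
        gid = f"G{g:05d}"
        tid = f"T{g:05d}.1"
        # two exons with one internal intron
        e1 = int(rng.integers(300, span // 2 - 100))
        intron = int(rng.integers(100, span // 4))
        exons = [
            GenomicInterval(chrom, start, start + e1, strand),
            GenomicInterval(chrom, start + e1 + intron, start + span, strand),
        ]
        t = TranscriptModel(tid, gid, exons, biotype)
        transcripts.append(t)
        if biotype == Biotype.MRNA:
            mrna_hosts.append(t)
        if biotype == Biotype.UNASSIGNED:
            artefact_candidates.append(len(transcripts) - 1)

    # re-position a fraction of unassigned transcripts as run-through
    # artefacts hugging a host mRNA's 3' end
    n_art = int(round(len(artefact_candidates) * config.artefact_fraction))
    artefact_ids: set[str] = set()
    art_idx = list(artefact_candidates[:n_art])
    # hosts long enough that the artefact's ±5 kb promoter window stays
    # clear of the host's own TSS marks (mark extent ≤ 2.5 kb)
    long_hosts = [h for h in mrna_hosts if h.end - h.start >= 2_800]
    for j, idx in enumerate(art_idx):
        if not long_hosts:
            break
        host = long_hosts[int(rng.integers(len(long_hosts)))]
        span = host.end - host.start
        gap = int(rng.integers(max(200, 7_600 - span), 4_800))
        length = int(rng.integers(400, 2_000))
        if host.strand == "+":
            start = host.end - 1 + gap
            iv = GenomicInterval(host.chrom, start, start + length, "+")
        else:
            end = host.start - gap
            if end - length < 0:
                continue
            iv = GenomicInterval(host.chrom, end - length, end, "-")
        old = transcripts[idx]
        transcripts[idx] = TranscriptModel(
            old.transcript_id, old.gene_id, [iv], Biotype.UNASSIGNED
        )
        artefact_ids.add(old.transcript_id)

    # write a long ORF into every mRNA's spliced sequence so that
    # coding-potential training sees genuine coding structure
    for t in transcripts:
        if t.biotype == Biotype.MRNA:
            _plant_orf(genome, t, rng, config.orf_coverage)

    from .genome import tss as _tss

    for t in transcripts:
        gene_rows.append(
            {
                "gene_id": t.gene_id,
                "biotype": t.biotype.value,
                "chrom": t.chrom,
                "tss": _tss(t),
                "strand": t.strand,
                "is_direct_target": False,
                "direction": "",
                "planted_site_pos": -1,
            }
        )
        tx_rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "label": "artefact" if t.transcript_id in artefact_ids else "genuine",
                "marked": False,
            }
        )

    truth = TruthTable(
        genes=pd.DataFrame(gene_rows),
        transcripts=pd.DataFrame(tx_rows),
        markers=pd.DataFrame(),
    )

    # choose planted direct targets among genuine (non-artefact) genes and
    # write a dimeric p53RE into the genome near each TSS
    genuine_mask = truth.transcripts["label"] == "genuine"
    eligible = truth.genes[genuine_mask.to_numpy()].reset_index(drop=True)
    if config.n_planted_targets > len(eligible):
        raise ValueError("more planted targets requested than eligible genes")
    pick = rng.choice(len(eligible), size=config.n_planted_targets, replace=False)
    pick = np.sort(pick)
    site = np.frombuffer(P53RE_CONSENSUS.encode(), dtype="S1")
    planted_pos: dict[str, int] = {}
    used: list[tuple[str, int]] = []
    for j in pick:
        row = eligible.iloc[int(j)]
        chrom, tss_pos = row["chrom"], int(row["tss"])
        for _ in range(100):
            # binding concentrates at the TSS and ~5 kb upstream of it
            centre = 0.0 if rng.random() < 0.5 else -5_000.0
            off = int(np.clip(rng.normal(centre, 1_500),
                              -config.site_offset_range, config.site_offset_range))
            if row["strand"] == "-":
                off = -off
            pos = tss_pos + off
            if pos < 0 or pos + len(site) > config.chromosome_length:
                continue
            if any(c == chrom and abs(p - pos) < 40 for c, p in used):
                continue
            break
        else:
            raise RuntimeError("could not place a planted site without collision")
        genome[chrom][pos : pos + len(site)] = site
        used.append((chrom, pos))
        planted_pos[row["gene_id"]] = pos
    up = rng.random(config.n_planted_targets) < config.de_up_fraction
    for k, (gid, pos) in enumerate(planted_pos.items()):
        i = truth.genes.index[truth.genes["gene_id"] == gid][0]
        truth.genes.at[i, "is_direct_target"] = True
        truth.genes.at[i, "direction"] = "up" if up[k] else "down"
        truth.genes.at[i, "planted_site_pos"] = pos
    return genome, transcripts, truth


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _plant_orf(
    genome: Mapping[str, np.ndarray],
    t: TranscriptModel,
    rng: np.random.Generator,
    coverage: float,
) -> None:
    """Overwrite the transcript's spliced sequence with one containing a
    long ATG→stop ORF (~``coverage`` of the spliced length)."""
    length = sum(len(e) for e in t.exons)
    n_codons = max(100, int(length * coverage) // 3)
    if 3 * n_codons > length:
        n_codons = length // 3
    body = "".join(
        _NON_STOP_CODONS[int(i)]
        for i in rng.integers(0, len(_NON_STOP_CODONS), size=n_codons - 2)
    )
    orf = "ATG" + body + "TAA"
    start = int(rng.integers(0, length - len(orf) + 1))
    flank = "".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=length - len(orf)))
    spliced = flank[:start] + orf + flank[start:]
    if t.strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        genomic = spliced.translate(comp)[::-1]
    else:
        genomic = spliced
    pos = 0
    arr = np.frombuffer(genomic.encode(), dtype="S1")
    for e in t.exons:
        n = len(e)
        genome[e.chrom][e.start : e.end] = arr[pos : pos + n]
        pos += n


def _apportion(total: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``total`` into exact counts."""
    raw = np.array(fractions, float) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


# --- peaks + coverage ---------------------------------------------------


def simulate_peaks_and_coverage(
    truth: TruthTable, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Treated/untreated narrowPeak tables plus a binned coverage track.

    Each planted target gets exactly one treated peak whose summit sits
    on the planted site (jittered but still covering it); decoys are
    placed uniformly, away from planted sites and outside ±10 kb of any
    TSS so they cannot create spurious proximal assignments. The
    untreated set is a subset of the treated peaks, emulating basal
    binding. Coverage = Gaussian bumps at treated summits plus uniform
    noise, emitted only where nonzero (absent bases read as zero).
    """
    rng = _spawn(config.seed, "peaks")
    half_peak = config.peak_width // 2
    rows = []
    planted = truth.genes[truth.genes["is_direct_target"]]
    for _, g in planted.iterrows():
        centre = int(g["planted_site_pos"]) + len(P53RE_CONSENSUS) // 2
        jitter = int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
        summit = centre + jitter
        start = max(0, summit - half_peak)
        rows.append(
            {
                "chrom": g["chrom"],
                "start": start,
                "end": start + config.peak_width,
                "name": f"peak_{g['gene_id']}",
                "signal": float(rng.uniform(20, 80)),
                "summit": summit - start,
                "planted": True,
            }
        )
    tss_by_chrom: dict[str, np.ndarray] = {
        str(c): grp["tss"].to_numpy(np.int64)
        for c, grp in truth.genes.groupby("chrom")
    }
    chroms = sorted(tss_by_chrom)
    non_target = truth.genes[~truth.genes["is_direct_target"]].reset_index(drop=True)
    min_sep = 2 * config.coverage_window + config.peak_width  # disjoint coverage

    def too_close(chrom: str, start: int) -> bool:
        return any(
            r["chrom"] == chrom and abs(r["start"] - start) < min_sep for r in rows
        )

    n_prox_decoys = int(round(config.n_decoy_peaks * config.decoy_proximal_fraction))
    n_dec = 0
    while n_dec < config.n_decoy_peaks:
        if n_dec < n_prox_decoys and len(non_target):
            # decoy bound near the TSS of a gene without planted DE signal
            g = non_target.iloc[int(rng.integers(len(non_target)))]
            chrom = str(g["chrom"])
            offset = int(rng.integers(500, 9_000)) * (1 if rng.random() < 0.5 else -1)
            mid = int(g["tss"]) + offset
            start = mid - half_peak
            if start < 0 or start + config.peak_width > config.chromosome_length:
                continue
        else:
            # background decoy, well away from every TSS
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chromosome_length - config.peak_width))
            mid = start + half_peak
            tsss = tss_by_chrom[chrom]
            if len(tsss) and np.abs(tsss - mid).min() <= 10_000 + config.peak_width:
                continue
        if too_close(chrom, start):
            continue
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + config.peak_width,
                "name": f"decoy_{n_dec:04d}",
                "signal": float(rng.uniform(5, 30)),
                "summit": half_peak,
                "planted": False,
            }
        )
        n_dec += 1
    treated = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    keep = rng.random(len(treated)) < config.untreated_fraction
    untreated = treated[keep].reset_index(drop=True)

    # coverage: Gaussian bump around each treated summit on a global
    # 10-bp grid (grid alignment lets overlapping windows share bins,
    # which are then summed, keeping the track non-overlapping)
    cov_rows = []
    w, b = config.coverage_window, config.coverage_bin
    for r in treated.itertuples(index=False):
        summit_abs = r.start + r.summit
        grid_lo = ((summit_abs - w) // b) * b
        starts = np.arange(grid_lo, summit_abs + w, b)
        centres = starts + b / 2 - summit_abs
        bump = config.coverage_bump_height * np.exp(
            -0.5 * (centres / config.coverage_bump_sd) ** 2
        )
        noise = rng.uniform(0, config.coverage_noise, size=len(starts))
        vals = np.round(bump + noise, 4)
        for s, v in zip(starts, vals):
            if s >= 0 and s + b <= config.chromosome_length:
                cov_rows.append(
                    {"chrom": r.chrom, "start": int(s), "end": int(s + b), "value": float(v)}
                )
    coverage = (
        pd.DataFrame(cov_rows)
        .groupby(["chrom", "start", "end"], as_index=False)["value"]
        .sum()
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    return treated, untreated, coverage


# --- expression tables --------------------------------------------------


def simulate_expression_tables(
    truth: TruthTable, config: SimulationConfig
) -> list[pd.DataFrame]:
    """Two independent replicate DE tables (transcript_id, log2fc,
    p_value, replicate).

    Null transcripts: p ~ U(0,1), log2FC ~ N(0, 0.2). Planted targets:
    p ~ Beta(a, 1) (a = 0.01, heavily sub-alpha), log2FC ~ sign·N(2,
    0.5) with the planted direction's sign. In noiseless mode planted
    p-values are fixed at 1e-6 and null p-values are drawn from
    U(5·alpha, 1), so the truth table is exactly recoverable.
    """
    rng = _spawn(config.seed, "expression")
    planted_dir = truth.genes.set_index("gene_id")["direction"].to_dict()
    is_target = truth.genes.set_index("gene_id")["is_direct_target"].to_dict()
    tables = []
    for rep in (1, 2):
        rows = []
        for t in truth.transcripts.itertuples(index=False):
            gid = t.gene_id
            if is_target.get(gid, False):
                sign = 1.0 if planted_dir[gid] == "up" else -1.0
                if config.noiseless:
                    p = 1e-6
                else:
                    p = float(rng.beta(config.de_planted_beta_a, 1.0))
                lfc = sign * abs(
                    rng.normal(config.de_planted_lfc_mean, config.de_planted_lfc_sd)
                )
            else:
                if config.noiseless:
                    p = float(rng.uniform(5 * config.de_alpha, 1.0))
                else:
                    p = float(rng.uniform())
                lfc = float(rng.normal(0.0, config.de_null_lfc_sd))
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "log2fc": round(float(lfc), 6),
                    "p_value": float(p),
                    "replicate": f"rep{rep}",
                }
            )
        tables.append(pd.DataFrame(rows))
    return tables


# --- chromatin marks ----------------------------------------------------


def simulate_marks(
    truth: TruthTable,
    transcripts: Sequence[TranscriptModel],
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """BED intervals per mark. A ``mark_fraction`` of genuine transcript
    5' ends carry at least one mark (centred within ±mark_jitter of the
    TSS); artefact transcripts never do."""
    from .chromatin import ACTIVE_MARKS
    from .genome import tss as _tss

    rng = _spawn(config.seed, "marks")
    label = truth.transcripts.set_index("transcript_id")["label"].to_dict()
    # exclusion zones: ±5 kb promoter windows of planted artefacts — the
    # triage filter must see those 5' ends as unmarked
    artefact_windows: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        if label[t.transcript_id] == "artefact":
            artefact_windows.setdefault(t.chrom, []).append(
                (_tss(t) - 5_000, _tss(t) + 5_000)
            )

    def clashes(chrom: str, start: int, end: int) -> bool:
        return any(
            start < hi and lo < end for lo, hi in artefact_windows.get(chrom, [])
        )

    beds: dict[str, list[dict]] = {m: [] for m in ACTIVE_MARKS}
    marked_flags = {}
    for t in transcripts:
        marked_flags[t.transcript_id] = False
        if label[t.transcript_id] == "artefact":
            continue
        if rng.random() >= config.mark_fraction:
            continue
        n_marks = 1 + int(rng.integers(0, len(ACTIVE_MARKS)))
        which = rng.choice(len(ACTIVE_MARKS), size=n_marks, replace=False)
        for mi in np.sort(which):
            for _ in range(50):
                centre = _tss(t) + int(
                    rng.integers(-config.mark_jitter, config.mark_jitter + 1)
                )
                start = max(0, centre - config.mark_width // 2)
                if not clashes(t.chrom, start, start + config.mark_width):
                    beds[ACTIVE_MARKS[mi]].append(
                        {"chrom": t.chrom, "start": start, "end": start + config.mark_width}
                    )
                    marked_flags[t.transcript_id] = True
                    break
    truth.transcripts["marked"] = truth.transcripts["transcript_id"].map(marked_flags)
    return {
        m: pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
        for m, rows in beds.items()
    }


# --- paired cohort ------------------------------------------------------


def simulate_cohort_arrays(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tumour ΔCt, normal ΔCt, marker baselines), shape (patients,
    markers).

    Model per patient i and marker g: normal ΔCt = μ_g + u_i + ε,
    tumour ΔCt = μ_g + δ_g + u_i + ε with u_i ~ N(0, τ²) shared within
    a patient and ε ~ N(0, σ²) independent per well.
    """
    rng = _spawn(config.seed, "cohort")
    deltas = np.asarray(config.marker_deltas, float)
    n, m = config.n_patients, len(deltas)
    mu = rng.uniform(4.0, 10.0, size=m)
    u = rng.normal(0.0, config.patient_sd, size=n)
    eps_n = rng.normal(0.0, config.cohort_sigma, size=(n, m))
    eps_t = rng.normal(0.0, config.cohort_sigma, size=(n, m))
    normal = mu[None, :] + u[:, None] + eps_n
    tumour = mu[None, :] + deltas[None, :] + u[:, None] + eps_t
    return tumour, normal, mu


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Long-format Ct table (patient, tissue, marker, ct, reference_ct)
    plus the marker truth (planted δ per marker). The reference gene Ct
    is constant; target Ct = reference + ΔCt."""
    tumour, normal, mu = simulate_cohort_arrays(config)
    deltas = np.asarray(config.marker_deltas, float)
    markers = [f"lnc{g + 1:02d}" for g in range(len(deltas))]
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        for tissue, mat in (("tumour", tumour), ("normal", normal)):
            for g, marker in enumerate(markers):
                rows.append(
                    {
                        "patient": pid,
                        "tissue": tissue,
                        "marker": marker,
                        "ct": round(config.reference_ct + float(mat[i, g]), 6),
                        "reference_ct": config.reference_ct,
                    }
                )
    truth = TruthTable(
        genes=pd.DataFrame(),
        transcripts=pd.DataFrame(),
        markers=pd.DataFrame({"marker": markers, "delta": deltas, "mu": mu}),
    )
    return pd.DataFrame(rows), truth


# --- file emission ------------------------------------------------------


def write_fasta(genome: Mapping[str, np.ndarray], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom].tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_narrowpeak(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df["name"],
            "score": 0,
            "strand": ".",
            "signalValue": df["signal"],
            "pValue": -1,
            "qValue": -1,
            "summit": df["summit"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write every pipeline input; returns a manifest of
    relative paths. Deterministic and byte-identical for a fixed
    config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, truth = simulate_genome_annotation(config)
    treated, untreated, coverage = simulate_peaks_and_coverage(truth, config)
    de_tables = simulate_expression_tables(truth, config)
    marks = simulate_marks(truth, transcripts, config)
    cohort, cohort_truth = simulate_cohort(config)
    truth.markers = cohort_truth.markers

    manifest: dict[str, str] = {}

    def save(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest[name.split(".")[0]] = name

    def _write_gtf(p: Path) -> None:
        with open(p, "w") as fh:
            write_annotation(transcripts, fh)

    save("genome.fa", lambda p: write_fasta(genome, p))
    save("annotation.gtf", _write_gtf)
    save("peaks_treated.narrowPeak", lambda p: write_narrowpeak(treated, p))
    save("peaks_untreated.narrowPeak", lambda p: write_narrowpeak(untreated, p))
    save(
        "coverage.bedGraph",
        lambda p: coverage.to_csv(p, sep="\t", header=False, index=False),
    )
    for i, tab in enumerate(de_tables, start=1):
        name = f"de_rep{i}.tsv"
        tab.to_csv(outdir / name, sep="\t", index=False)
        manifest[f"de_rep{i}"] = name
    for mark, bed in marks.items():
        name = f"mark_{mark}.bed"
        bed.to_csv(outdir / name, sep="\t", header=False, index=False)
        manifest[f"mark_{mark}"] = name
    save("cohort_ct.tsv", lambda p: cohort.to_csv(p, sep="\t", index=False))
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t", index=False)
    truth.markers.to_csv(outdir / "truth_markers.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    for extra in ("truth_genes.tsv", "truth_transcripts.tsv", "truth_markers.tsv", "truth.json"):
        manifest[extra.split(".")[0]] = extra
    (outdir / "config.json").write_text(
        json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(config).items()
             if k != "biotype_mix"}
            | {"biotype_mix": {b.value: f for b, f in config.biotype_mix.items()}},
            indent=1,
        )
    )
    manifest["config"] = "config.json"
    return manifest


def validate_outputs(outdir: str | Path) -> None:
    """Cross-check emitted files against the truth table: every planted
    site is literally present in the FASTA, every planted target has a
    covering treated peak and a significant DE record."""
    from .coding import read_fasta

    outdir = Path(outdir)
    genome = read_fasta(outdir / "genome.fa")
    truth_genes = pd.read_csv(outdir / "truth_genes.tsv", sep="\t")
    treated = pd.read_csv(outdir / "peaks_treated.narrowPeak", sep="\t", header=None)
    de = [pd.read_csv(outdir / f"de_rep{i}.tsv", sep="\t") for i in (1, 2)]
    planted = truth_genes[truth_genes["is_direct_target"]]
    for _, g in planted.iterrows():
        pos = int(g["planted_site_pos"])
        seq = genome[g["chrom"]][pos : pos + len(P53RE_CONSENSUS)]
        if seq != P53RE_CONSENSUS:
            raise AssertionError(f"planted site missing for {g['gene_id']}")
        hits = treated[
            (treated[0] == g["chrom"]) & (treated[1] <= pos) & (treated[2] >= pos + 20)
        ]
        if hits.empty:
            raise AssertionError(f"no treated peak covers the site of {g['gene_id']}")
        tids = set(
            pd.read_csv(outdir / "truth_transcripts.tsv", sep="\t")
            .query("gene_id == @g.gene_id")["transcript_id"]
        )
        sig = any(
            ((tab["transcript_id"].isin(tids)) & (tab["p_value"] < 0.01)).any()
            for tab in de
        )
        if not sig:
            raise AssertionError(f"planted target {g['gene_id']} has no DE record")
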