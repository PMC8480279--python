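"""Synthetic inputs for the screening pipeline.

Everything the downstream stages consume can be generated here under an
explicit seed: arrayed 384-well plate layouts with in-plate empty-vector
controls, well-level reporter readouts (GFP+ fraction for NF-kB, puncta per
live cell for LC3, F420/F485 channel pairs for the ratiometric redox
sensor), per-cell tables and rendered well images, cosmid-insert libraries
with planted overlap groups, transposon-mutant panels with Sanger-style
flanking reads, and per-patient protein catalogs with planted homologs.

The generators model the statistical structure the analysis assumes — null
wells Gaussian around the control level, actives shifted by a configurable
number of control SDs, toxicity as an elevated dead-cell fraction — not the
biology of any real stool community.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqs import random_dna, random_protein, revcomp

ASSAYS = ("nfkb", "lc3", "sonar")

ROW_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SimConfig:
    """Study-condition knobs for the simulated screen.

    ``null_mean``/``null_sd`` are in readout units (e.g. GFP+ fraction);
    ``active_effect`` is an effect size in units of ``null_sd``, matching
    how plate Z-scores are computed. ``reproducibility`` is the per-replicate
    probability that a planted active stays active in a validation replicate.
    """

    seed: int = 0
    n_plates: int = 1
    plate_rows: int = 16
    plate_cols: int = 24
    n_controls_per_plate: int = 42
    control_cols: tuple[int, ...] = (1, 12, 23)  # 1-based plate columns
    null_mean: float = 0.05
    null_sd: float = 0.01
    active_effect: float = 8.0
    active_fraction: float = 0.013
    toxic_fraction: float = 0.01
    toxic_death_fraction: float = 0.8
    baseline_death_mean: float = 0.05
    baseline_death_sd: float = 0.015
    reproducibility: float = 0.9
    sonar_f485_mean: float = 1000.0
    sonar_f485_sd: float = 30.0

    def __post_init__(self) -> None:
        if self.plate_rows * self.plate_cols < self.n_controls_per_plate:
            raise ValueError("plate has fewer wells than requested controls")
        for name in ("active_fraction", "toxic_fraction", "toxic_death_fraction",
                     "reproducibility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.null_sd <= 0:
            raise ValueError("null_sd must be positive")

    @property
    def wells_per_plate(self) -> int:
        return self.plate_rows * self.plate_cols

    @property
    def clone_wells_per_plate(self) -> int:
        return self.wells_per_plate - self.n_controls_per_plate

    def control_positions(self) -> list[tuple[int, int]]:
        """0-based (row, col) control positions: fixed columns, top rows first."""
        n_rows_used = math.ceil(self.n_controls_per_plate / len(self.control_cols))
        pos = [(r, c - 1) for c in self.control_cols for r in range(n_rows_used)]
        return pos[: self.n_controls_per_plate]


@dataclass
class CloneInsert:
    """A cosmid's metagenomic insert with optional ground-truth provenance."""

    clone_id: str
    sequence: str
    source_genome: str | None = None
    source_interval: tuple[int, int] | None = None  # 0-based half-open
    source_strand: str | None = None  # "+" or "-"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("insert sequence must be non-empty")
        if self.source_interval is not None:
            s, e = self.source_interval
            if e - s != len(self.sequence):
                raise ValueError("insert length must equal provenance interval length")


@dataclass
class CloneLibrary:
    """Arrayed clone inserts plus the planted region partition (ground truth)."""

    inserts: list[CloneInsert]
    truth_regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.inserts]
        if len(set(ids)) != len(ids):
            raise ValueError("clone ids must be unique")


# ---------------------------------------------------------------------------
# genomes and clone libraries
# ---------------------------------------------------------------------------

def gen_genomes(n: int, length: int, gc: float = 0.5, seed: int = 0) -> list[str]:
    """``n`` i.i.d. random genomes of ``length`` bp at GC fraction ``gc``."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return [random_dna(rng, length, gc) for _ in range(n)]


def _truncated_normal_int(rng: np.random.Generator, mean: float, sd: float,
                          lo: int) -> int:
    v = lo - 1
    while v < lo:
        v = int(round(rng.normal(mean, sd)))
    return v


class _LocusAllocator:
    """Greedy allocation of disjoint loci across a list of genomes, with gaps
    so that inserts from different regions cannot share sequence."""

    def __init__(self, genomes: list[str], gap: int = 1000):
        self.genomes = genomes
        self.gap = gap
        self.genome_idx = 0
        self.cursor = 0

    def take(self, span: int) -> tuple[int, int]:
        while self.genome_idx < len(self.genomes):
            if self.cursor + span <= len(self.genomes[self.genome_idx]):
                start = self.cursor
                self.cursor += span + self.gap
                return self.genome_idx, start
            self.genome_idx += 1
            self.cursor = 0
        raise ValueError("genomes too short to allocate all requested loci")


def gen_clone_library(
    genomes: list[str],
    n_clones: int,
    insert_mean: int = 30_000,
    insert_sd: int = 2_000,
    planted_groups: list[tuple[int, int]] | None = None,
    seed: int = 0,
    min_insert: int = 15_000,
    id_prefix: str = "C",
) -> CloneLibrary:
    """Sample a cosmid-insert library with planted overlap groups.

    Each planted group ``(group_size, overlap_bp)`` is tiled across one
    shared locus so every adjacent pair of inserts shares exactly
    ``overlap_bp`` of identical sequence; all remaining clones come from
    disjoint loci. Insert lengths are Normal(insert_mean, insert_sd)
    truncated at ``min_insert``. About half of all inserts are stored
    reverse-complemented. ``truth_regions`` records the planted partition.
    """
    planted_groups = planted_groups or []
    rng = np.random.default_rng(seed)
    n_grouped = sum(size for size, _ in planted_groups)
    if n_grouped > n_clones:
        raise ValueError("planted groups contain more clones than n_clones")

    alloc = _LocusAllocator(genomes)
    inserts: list[CloneInsert] = []
    truth: dict[str, str] = {}
    clone_no = 0
    region_no = 0

    def next_ids() -> tuple[str, str]:
        nonlocal clone_no
        clone_no += 1
        return f"{id_prefix}{clone_no:04d}", f"R{region_no:03d}"

    for size, overlap_bp in planted_groups:
        region_no += 1
        length = _truncated_normal_int(rng, insert_mean, insert_sd, min_insert)
        if overlap_bp >= length:
            raise ValueError(
                f"overlap_bp={overlap_bp} must be smaller than insert length {length}")
        step = length - overlap_bp
        span = length + (size - 1) * step
        gi, locus_start = alloc.take(span)
        for i in range(size):
            cid, rid = next_ids()
            s = locus_start + i * step
            seq = genomes[gi][s:s + length]
            strand = "+"
            if rng.random() < 0.5:
                seq, strand = revcomp(seq), "-"
            inserts.append(CloneInsert(cid, seq, f"G{gi}", (s, s + length), strand))
            truth[cid] = rid

    for _ in range(n_clones - n_grouped):
        region_no += 1
        length = _truncated_normal_int(rng, insert_mean, insert_sd, min_insert)
        gi, s = alloc.take(length)
        cid, rid = next_ids()
        seq = genomes[gi][s:s + length]
        strand = "+"
        if rng.random() < 0.5:
            seq, strand = revcomp(seq), "-"
        inserts.append(CloneInsert(cid, seq, f"G{gi}", (s, s + length), strand))
        truth[cid] = rid

    return CloneLibrary(inserts=inserts, truth_regions=truth)


# ---------------------------------------------------------------------------
# plate layouts and the well-level screen
# ---------------------------------------------------------------------------

def gen_plate_layouts(n_clones: int, cfg: SimConfig,
                      clone_ids: list[str] | None = None) -> pd.DataFrame:
    """Array ``n_clones`` clones into 384-well plates in arraying order.

    Every plate carries exactly ``cfg.n_controls_per_plate`` empty-vector
    control wells at the fixed control positions; the last plate may be
    partially filled. Returns one row per occupied well with columns
    plate_id, row (letter), col (1-based), role, clone_id.
    """
    if clone_ids is None:
        clone_ids = [f"C{i + 1:05d}" for i in range(n_clones)]
    if len(clone_ids) != n_clones:
        raise ValueError("clone_ids length must equal n_clones")
    control_set = set(cfg.control_positions())
    clone_positions = [
        (r, c)
        for r in range(cfg.plate_rows)
        for c in range(cfg.plate_cols)
        if (r, c) not in control_set
    ]
    rows = []
    n_plates = math.ceil(n_clones / cfg.clone_wells_per_plate) if n_clones else 0
    it = iter(clone_ids)
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        for r, c in sorted(control_set):
            rows.append((plate_id, ROW_LETTERS[r], c + 1, "control", None))
        for r, c in clone_positions:
            cid = next(it, None)
            if cid is None:
                break
            rows.append((plate_id, ROW_LETTERS[r], c + 1, "clone", cid))
    return pd.DataFrame(rows, columns=["plate_id", "row", "col", "role", "clone_id"])


def simulate_screen(
    layouts: pd.DataFrame,
    active_set: set[str],
    cfg: SimConfig,
    assay: str = "nfkb",
    replicates: int = 1,
    seed: int = 0,
    active_by_replicate: dict[int, set[str]] | None = None,
) -> pd.DataFrame:
    """Simulate well readouts for one assay over ``replicates`` passes.

    Control and null clone wells draw ~ Normal(null_mean, null_sd); wells in
    ``active_set`` draw ~ Normal(null_mean + active_effect*null_sd, null_sd).
    In replicates after the first, each planted active reverts to the null
    distribution with probability 1 - cfg.reproducibility, independently per
    replicate (pass ``active_by_replicate`` to plant replicate activity
    explicitly instead). A ``toxic_fraction`` of clones gets death fraction
    ``toxic_death_fraction``; others draw a small baseline. The ratiometric
    sensor emits (f420, f485) channel pairs whose ratio carries the
    null/active structure; the other assays emit the readout directly.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    clone_ids = set(layouts.loc[layouts.role == "clone", "clone_id"])
    if not active_set <= clone_ids:
        raise ValueError("active_set contains clone ids absent from the layouts")
    rng = np.random.default_rng(seed)

    all_clones = sorted(clone_ids)
    n_toxic = int(round(cfg.toxic_fraction * len(all_clones)))
    toxic = set(rng.choice(all_clones, size=n_toxic, replace=False)) if n_toxic else set()

    out = []
    for rep in range(1, replicates + 1):
        df = layouts.copy()
        df["replicate"] = rep
        n = len(df)
        is_clone = (df.role == "clone").to_numpy()
        if active_by_replicate is not None:
            rep_active = active_by_replicate.get(rep, set())
            active = df.clone_id.isin(rep_active).to_numpy() & is_clone
        else:
            active = df.clone_id.isin(active_set).to_numpy() & is_clone
            if rep > 1:
                keep = rng.random(n) < cfg.reproducibility
                active &= keep
        mean = np.where(active, cfg.null_mean + cfg.active_effect * cfg.null_sd,
                        cfg.null_mean)
        value = rng.normal(mean, cfg.null_sd)
        death = np.clip(rng.normal(cfg.baseline_death_mean, cfg.baseline_death_sd, n),
                        0.0, 1.0)
        death = np.where(df.clone_id.isin(toxic).to_numpy() & is_clone,
                         cfg.toxic_death_fraction, death)
        if assay == "sonar":
            f485 = rng.normal(cfg.sonar_f485_mean, cfg.sonar_f485_sd, n)
            df["f420"] = value * f485
            df["f485"] = f485
            df["readout"] = np.nan
        else:
            df["f420"] = np.nan
            df["f485"] = np.nan
            df["readout"] = np.clip(value, 0.0, None)
        df["death_fraction"] = death
        df["qc_failed"] = False
        out.append(df)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# per-cell simulation and well-image rendering
# ---------------------------------------------------------------------------

def simulate_cells(n_cells: int, death_p: float, gfp_p: float,
                   puncta_lambda: float, seed: int = 0) -> pd.DataFrame:
    """Per-cell ground truth: dead ~ Bern(death_p); live cells get
    gfp_positive ~ Bern(gfp_p) and puncta ~ Poisson(puncta_lambda)."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    for name, p in (("death_p", death_p), ("gfp_p", gfp_p)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if puncta_lambda < 0:
        raise ValueError("puncta_lambda must be >= 0")
    rng = np.random.default_rng(seed)
    dead = rng.random(n_cells) < death_p
    gfp = (rng.random(n_cells) < gfp_p) & ~dead
    puncta = np.where(dead, 0, rng.poisson(puncta_lambda, n_cells))
    return pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "dead": dead,
        "gfp_positive": gfp,
        "puncta": puncta.astype(int),
    })


# offsets (dy, dx) inside a cell where puncta may be stamped; all pairwise
# distances >= 3.4 px so neighbouring puncta stay resolvable at sigma ~1.2
_PUNCTA_OFFSETS = [(0.0, 0.0)]
_PUNCTA_OFFSETS += [(3.8 * math.sin(2 * math.pi * i / 6),
                     3.8 * math.cos(2 * math.pi * i / 6)) for i in range(6)]
_PUNCTA_OFFSETS += [(7.0 * math.sin(2 * math.pi * (i + 0.5) / 10),
                     7.0 * math.cos(2 * math.pi * (i + 0.5) / 10)) for i in range(10)]

DAPI, TEXAS_RED, FITC = 0, 1, 2

NUCLEUS_AMP = 1.0
PI_AMP = 1.0
PUNCTUM_AMP = 1.0
PUNCTUM_SIGMA = 1.2
GFP_DIFFUSE = 0.35
LIVE_DIFFUSE = 0.08


def _stamp_gaussian(img: np.ndarray, y: float, x: float, amp: float,
                    sigma: float) -> None:
    r = int(math.ceil(4 * sigma))
    y0, x0 = int(round(y)), int(round(x))
    ys = slice(max(0, y0 - r), min(img.shape[0], y0 + r + 1))
    xs = slice(max(0, x0 - r), min(img.shape[1], x0 + r + 1))
    yy, xx = np.mgrid[ys, xs]
    img[ys, xs] += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))


def _stamp_disk(img: np.ndarray, y: float, x: float, amp: float,
                radius: float) -> None:
    r = int(math.ceil(radius)) + 1
    y0, x0 = int(round(y)), int(round(x))
    ys = slice(max(0, y0 - r), min(img.shape[0], y0 + r + 1))
    xs = slice(max(0, x0 - r), min(img.shape[1], x0 + r + 1))
    yy, xx = np.mgrid[ys, xs]
    img[ys, xs] += amp * (((yy - y) ** 2 + (xx - x) ** 2) <= radius ** 2)


def render_well_image(
    cells: pd.DataFrame,
    size: int = 512,
    psf_sigma: float = 2.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    cell_radius: float = 10.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 3-channel (DAPI, Texas red, FITC) well image.

    Each nucleus is a Gaussian spot in the DAPI channel; Texas-red spots
    appear only at dead cells; FITC carries a diffuse disk for GFP+ cells
    plus one punctate maximum per simulated punctum, all inside the cell
    radius; additive Gaussian background noise on every channel. Cells are
    placed on a jittered grid so no two cells overlap. Returns the float
    image (3, size, size) and the ground-truth table with (y, x) centers.
    """
    rng = np.random.default_rng(seed)
    n = len(cells)
    spacing = int(2 * cell_radius + 6)
    margin = int(cell_radius + 4)
    slots_1d = np.arange(margin, size - margin, spacing)
    slots = [(float(y), float(x)) for y in slots_1d for x in slots_1d]
    if n > len(slots):
        raise ValueError(
            f"cannot place {n} cells without overlap at size={size} "
            f"(capacity {len(slots)})")
    order = rng.permutation(len(slots))[:n]
    jitter = rng.uniform(-2.0, 2.0, size=(n, 2))

    img = np.zeros((3, size, size), dtype=np.float64)
    truth = cells.copy().reset_index(drop=True)
    ys, xs = [], []
    for i in range(n):
        y, x = slots[order[i]]
        y += jitter[i, 0]
        x += jitter[i, 1]
        ys.append(y)
        xs.append(x)
        row = truth.iloc[i]
        _stamp_gaussian(img[DAPI], y, x, NUCLEUS_AMP, psf_sigma)
        if row.dead:
            _stamp_gaussian(img[TEXAS_RED], y, x, PI_AMP, psf_sigma)
            continue
        _stamp_disk(img[FITC], y, x, LIVE_DIFFUSE, cell_radius)
        if row.gfp_positive:
            _stamp_disk(img[FITC], y, x, GFP_DIFFUSE, cell_radius)
        n_puncta = int(row.puncta)
        if n_puncta > len(_PUNCTA_OFFSETS):
            raise ValueError(
                f"cell with {n_puncta} puncta exceeds placement capacity "
                f"{len(_PUNCTA_OFFSETS)}")
        offs = [_PUNCTA_OFFSETS[j]
                for j in rng.permutation(len(_PUNCTA_OFFSETS))[:n_puncta]]
        for dy, dx in offs:
            _stamp_gaussian(img[FITC], y + dy, x + dx, PUNCTUM_AMP, PUNCTUM_SIGMA)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    truth["y"] = ys if n else pd.Series(dtype=float)
    truth["x"] = xs if n else pd.Series(dtype=float)
    return img, truth


# ---------------------------------------------------------------------------
# transposon panels
# ---------------------------------------------------------------------------

def gen_coding_sequence(rng: np.random.Generator, length_nt: int) -> str:
    """ATG + stop-free random codons + TAA, total length ``length_nt``."""
    if length_nt % 3 != 0 or length_nt < 9:
        raise ValueError("length_nt must be a multiple of 3 and >= 9")
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < length_nt // 3 - 2:
        c = random_dna(rng, 3)
        if c not in stops and c != "ATG":
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def make_insert_with_operon(
    n_genes: int,
    gene_len: int = 999,
    intergenic: int = 200,
    flank: int = 2_000,
    seed: int = 0,
) -> tuple[str, list[tuple[int, int]]]:
    """A synthetic insert carrying an operon of ``n_genes`` forward-strand
    genes, returning the sequence and 0-based half-open gene intervals."""
    rng = np.random.default_rng(seed)
    parts = [random_dna(rng, flank)]
    genes = []
    pos = flank
    for _ in range(n_genes):
        cds = gen_coding_sequence(rng, gene_len)
        genes.append((pos, pos + len(cds)))
        parts.append(cds)
        pos += len(cds)
        parts.append(random_dna(rng, intergenic))
        pos += intergenic
    parts.append(random_dna(rng, flank))
    return "".join(parts), genes


def gen_transposon_panel(
    clone: CloneInsert,
    genes: list[tuple[int, int]],
    effector_gene: int,
    n_mutants: int,
    cfg: SimConfig,
    seed: int = 0,
    n_replicates: int = 4,
    read_len: int = 200,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Random Tn5-style insertions over a clone insert.

    Insertion coordinates are uniform over the insert; a mutant whose
    coordinate falls inside the designated effector gene loses activity
    (its replicate readouts revert to the null distribution), all others
    keep active-level readouts. Each mutant gets a flanking read: the
    ``read_len`` bp immediately 3' of the insertion point, reverse-
    complemented for half of the mutants. Returns a mutant table
    (mutant_id, insertion_pos, truth_inactive, replicate readouts) and a
    dict of flanking reads.
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be >= 1")
    if not 0 <= effector_gene < len(genes):
        raise ValueError("effector_gene must index genes")
    rng = np.random.default_rng(seed)
    L = len(clone.sequence)
    positions = rng.integers(0, L - read_len, size=n_mutants)
    gs, ge = genes[effector_gene]
    inactive = (positions >= gs) & (positions < ge)
    active_mean = cfg.null_mean + cfg.active_effect * cfg.null_sd
    means = np.where(inactive, cfg.null_mean, active_mean)
    acts = rng.normal(means[:, None], cfg.null_sd, size=(n_mutants, n_replicates))
    flip = rng.random(n_mutants) < 0.5
    reads, rows = {}, []
    for i in range(n_mutants):
        mid = f"{clone.clone_id}_tn{i + 1:03d}"
        read = clone.sequence[positions[i]:positions[i] + read_len]
        if flip[i]:
            read = revcomp(read)
        reads[mid] = read
        rows.append((mid, int(positions[i]), bool(inactive[i]), *acts[i]))
    cols = ["mutant_id", "insertion_pos", "truth_inactive"]
    cols += [f"activity_{r + 1}" for r in range(n_replicates)]
    return pd.DataFrame(rows, columns=cols), reads


# ---------------------------------------------------------------------------
# patient protein catalogs
# ---------------------------------------------------------------------------

def mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    """I.i.d. point substitutions (always to a different residue) at ``rate``."""
    from .seqs import AA_ALPHABET
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must be in [0, 1]")
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [a for a in AA_ALPHABET if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def gen_patient_catalogs(
    n_patients: int,
    queries: list[str],
    planting: dict[int, list[tuple[int, float]]],
    decoys_per_patient: int = 8,
    seed: int = 0,
    decoy_len_mean: int = 300,
    decoy_len_sd: int = 50,
) -> list[list[tuple[str, str]]]:
    """Per-patient protein catalogs with planted query homologs.

    ``planting`` maps patient index -> list of (query index, mutation rate);
    each planted homolog is the query with i.i.d. point substitutions over
    its full length. Decoys are unrelated random proteins of comparable
    length. Returns one list of (protein_id, sequence) per patient.
    """
    if not queries:
        raise ValueError("queries must be non-empty")
    rng = np.random.default_rng(seed)
    catalogs = []
    for p in range(n_patients):
        entries: list[tuple[str, str]] = []
        for j, (qi, rate) in enumerate(planting.get(p, [])):
            entries.append((f"pat{p:03d}_hom{j}_q{qi}",
                            mutate_protein(rng, queries[qi], rate)))
        for d in range(decoys_per_patient):
            ln = max(50, int(round(rng.normal(decoy_len_mean, decoy_len_sd))))
            entries.append((f"pat{p:03d}_decoy{d}", random_protein(rng, ln)))
        catalogs.append(entries)
    return catalogs
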