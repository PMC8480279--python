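"""End-to-end orchestration: simulate -> screen -> validate -> dereplicate
-> transposon mapping -> prevalence, plus the planted study-shaped fixture.

``make_paper_fixture`` builds a fully synthetic dataset whose *planted
structure* carries the headline tallies of the original screen: 38,000
clones assayed; 499/339/182 primary actives for the NF-kB, LC3, and redox
assays; 86/5/1 of them validating under the 3-of-4 replicate rule; 82
NF-kB clones partitioning into 37 singletons plus 45 clones in 10 overlap
groups (47 effector regions); and 163 of 286 patient catalogs carrying at
least one effector homolog. Counts are structural — which clones are
active, which replicates reproduce, where overlaps are planted — while
the well-level noise is reseeded freely, so the pipeline recovers the same
tallies for any seed. To guarantee that, clone-well noise in the fixture
is drawn anchored to each plate's realized control statistics (null wells
inside |Z| < 2.5, actives at +8 control SDs), which pins the recomputed
Z-scores to the planted design. The unconditioned stochastic simulator in
``fmscreen.synthetic`` is the one used for null-calibration and power
studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dereplication, prevalence, screening, synthetic
from . import transposon as tn
from .io import write_fasta, write_tsv
from .screening import PlateStats, ScreenSummary
from .synthetic import CloneInsert, CloneLibrary, SimConfig

#: headline tallies of the screen: per assay (n primary actives, n validated)
PLANTED_COUNTS = {"nfkb": (499, 86), "lc3": (339, 5), "sonar": (182, 1)}
N_ASSAYED = 38_000
#: NF-kB dereplication structure: 10 overlap groups totalling 45 clones,
#: plus 37 singleton clones -> 47 regions from 82 clones
NFKB_GROUP_SIZES = (8, 7, 6, 5, 4, 4, 3, 3, 3, 2)
NFKB_N_SINGLETONS = 37
PLANTED_OVERLAP_BP = 8_000
N_PATIENTS = 286
N_PATIENTS_WITH_MATCH = 163
N_QUERIES = 11
HOMOLOG_MUTATION_RATE = 0.02
DECOY_MUTATION_RATE = 0.20

#: per-assay readout scales for the simulated screens
ASSAY_CONFIGS = {
    "nfkb": dict(null_mean=0.05, null_sd=0.01),   # live GFP+ fraction
    "lc3": dict(null_mean=0.5, null_sd=0.1),      # puncta per live cell
    "sonar": dict(null_mean=1.0, null_sd=0.05),   # F420/F485 ratio
}


@dataclass
class PaperFixture:
    """All synthetic inputs for one end-to-end run."""

    seed: int
    screens: dict[str, dict[str, pd.DataFrame]]
    candidates: dict[str, list[str]]
    validated: dict[str, list[str]]
    nfkb_library: CloneLibrary
    lc3_library: CloneLibrary
    tn_panels: list[dict]
    queries: dict[str, str]
    catalogs: list[list[tuple[str, str]]]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    screen_summaries: dict[str, ScreenSummary]
    region_summaries: dict[str, dict[str, int]]
    nominations: list[dict]
    prevalence: prevalence.PrevalenceTable

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "screens": {a: vars(s) for a, s in self.screen_summaries.items()},
            "regions": self.region_summaries,
            "nominations": self.nominations,
            "prevalence": {
                "per_query_counts": self.prevalence.per_query_counts,
                "n_patients": self.prevalence.n_patients,
                "n_patients_any": self.prevalence.n_patients_any,
                "pct_any": self.prevalence.pct_any,
            },
        }


# ---------------------------------------------------------------------------
# anchored well generation (fixture only)
# ---------------------------------------------------------------------------

def _anchored_plate_wells(
    clone_ids: list[str],
    active: set[str],
    cfg: SimConfig,
    assay: str,
    plate_prefix: str,
    replicate: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Well table whose recomputed per-plate Z-scores are pinned by design:
    null clone wells land strictly inside |Z| < 2.5 of their own plate's
    control statistics, active wells at +active_effect control SDs."""
    layout = synthetic.gen_plate_layouts(len(clone_ids), cfg, clone_ids=clone_ids)
    layout = layout.copy()
    layout["plate_id"] = plate_prefix + layout["plate_id"]
    parts = []
    for _, plate in layout.groupby("plate_id", sort=True):
        plate = plate.copy()
        is_ctl = (plate.role == "control").to_numpy()
        ctl_vals = rng.normal(cfg.null_mean, cfg.null_sd, int(is_ctl.sum()))
        m_hat = ctl_vals.mean()
        s_hat = ctl_vals.std(ddof=1)
        n = len(plate)
        u = np.clip(rng.normal(0.0, 1.0, n), -2.49, 2.49)
        is_active = plate.clone_id.isin(active).to_numpy()
        value = m_hat + s_hat * (u + np.where(is_active, cfg.active_effect, 0.0))
        value[is_ctl] = np.repeat(ctl_vals, 1)
        plate["replicate"] = replicate
        if assay == "sonar":
            f485 = rng.normal(cfg.sonar_f485_mean, cfg.sonar_f485_sd, n)
            plate["f420"] = value * f485
            plate["f485"] = f485
            plate["readout"] = np.nan
        else:
            plate["f420"] = np.nan
            plate["f485"] = np.nan
            plate["readout"] = value
        plate["death_fraction"] = np.clip(
            rng.normal(cfg.baseline_death_mean, cfg.baseline_death_sd, n), 0.0, 0.4)
        plate["qc_failed"] = False
        parts.append(plate)
    return pd.concat(parts, ignore_index=True)


def _fixture_screen(
    assay: str,
    n_primary: int,
    n_validated: int,
    seed: int,
    rng: np.random.Generator,
) -> tuple[dict[str, pd.DataFrame], list[str], list[str]]:
    cfg = SimConfig(seed=seed, **ASSAY_CONFIGS[assay])
    clone_ids = [f"C{i + 1:05d}" for i in range(N_ASSAYED)]
    primary_active = sorted(rng.choice(clone_ids, size=n_primary, replace=False))
    primary = _anchored_plate_wells(clone_ids, set(primary_active), cfg, assay,
                                    f"{assay[:2].upper()}-", 1, rng)
    validated = sorted(rng.choice(primary_active, size=n_validated, replace=False))
    validated_set = set(validated)
    # validators stay active in all four replicates; the rest reproduce in
    # at most two, so the 3-of-4 rule recovers the planted count exactly
    n_pass_fail = rng.integers(0, 3, size=len(primary_active))
    reps_active: dict[str, set[int]] = {}
    for cid, k in zip(primary_active, n_pass_fail):
        if cid in validated_set:
            reps_active[cid] = {1, 2, 3, 4}
        else:
            reps_active[cid] = set(rng.choice([1, 2, 3, 4], size=k, replace=False))
    val_parts = []
    for rep in (1, 2, 3, 4):
        rep_active = {cid for cid, reps in reps_active.items() if rep in reps}
        val_parts.append(_anchored_plate_wells(
            primary_active, rep_active, cfg, assay,
            f"{assay[:2].upper()}V{rep}-", rep, rng))
    return ({"primary": primary, "validation": pd.concat(val_parts, ignore_index=True)},
            primary_active, validated)


# ---------------------------------------------------------------------------
# fixture assembly
# ---------------------------------------------------------------------------

def _rename_lc3_clones(lib: CloneLibrary) -> CloneLibrary:
    # planted groups come out as (C0001,C0002), (C0003,C0004) + C0005;
    # rename to the L-series ids so the two regions are L001+L004 and
    # L002+L005 with L003 unique
    mapping = {"C0001": "L001", "C0002": "L004", "C0003": "L002",
               "C0004": "L005", "C0005": "L003"}
    inserts = [CloneInsert(mapping[c.clone_id], c.sequence, c.source_genome,
                           c.source_interval, c.source_strand)
               for c in lib.inserts]
    truth = {mapping[cid]: rid for cid, rid in lib.truth_regions.items()}
    return CloneLibrary(inserts=inserts, truth_regions=truth)


def make_paper_fixture(seed: int = 0) -> PaperFixture:
    """Full synthetic dataset reproducing the screen's headline tallies."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2021]))
    screens, candidates, validated = {}, {}, {}
    for assay, (n_primary, n_val) in PLANTED_COUNTS.items():
        screens[assay], candidates[assay], validated[assay] = _fixture_screen(
            assay, n_primary, n_val, seed, rng)

    # NF-kB active-clone library with the planted overlap partition
    groups = [(size, PLANTED_OVERLAP_BP) for size in NFKB_GROUP_SIZES]
    n_clones = sum(NFKB_GROUP_SIZES) + NFKB_N_SINGLETONS
    genome_len = _library_genome_length(NFKB_GROUP_SIZES, NFKB_N_SINGLETONS)
    genomes = synthetic.gen_genomes(1, genome_len, gc=0.45,
                                    seed=int(rng.integers(2**31)))
    nfkb_library = synthetic.gen_clone_library(
        genomes, n_clones, planted_groups=groups,
        seed=int(rng.integers(2**31)), id_prefix="N")

    lc3_genomes = synthetic.gen_genomes(1, 250_000, gc=0.45,
                                        seed=int(rng.integers(2**31)))
    lc3_library = _rename_lc3_clones(synthetic.gen_clone_library(
        lc3_genomes, 5, planted_groups=[(2, PLANTED_OVERLAP_BP),
                                        (2, PLANTED_OVERLAP_BP)],
        seed=int(rng.integers(2**31))))

    # transposon panels for three representative uncharacterized regions
    tn_panels = []
    cfg = SimConfig(seed=seed, **ASSAY_CONFIGS["nfkb"])
    for i in range(3):
        insert_seq, genes = synthetic.make_insert_with_operon(
            n_genes=5, seed=int(rng.integers(2**31)))
        clone = CloneInsert(f"TN{i + 1:02d}", insert_seq)
        effector = 2
        mutants_df, reads = synthetic.gen_transposon_panel(
            clone, genes, effector, n_mutants=40, cfg=cfg,
            seed=int(rng.integers(2**31)))
        tn_panels.append({"clone": clone, "genes": genes,
                          "effector_index": effector,
                          "mutants": mutants_df, "reads": reads})

    # patient catalogs: 163 of 286 carry a near-identical homolog of at
    # least one query; a third of the rest carry only a diverged homolog
    qrng = np.random.default_rng(np.random.SeedSequence([seed, 286]))
    queries = {f"Q{i + 1:02d}": _random_query(qrng) for i in range(N_QUERIES)}
    qids = list(queries)
    planting: dict[int, list[tuple[int, float]]] = {}
    for p in range(N_PATIENTS_WITH_MATCH):
        planting[p] = [(p % N_QUERIES, HOMOLOG_MUTATION_RATE)]
    for p in range(N_PATIENTS_WITH_MATCH, N_PATIENTS):
        if p % 3 == 0:
            planting[p] = [(p % N_QUERIES, DECOY_MUTATION_RATE)]
    catalogs = synthetic.gen_patient_catalogs(
        N_PATIENTS, [queries[q] for q in qids], planting,
        decoys_per_patient=8, seed=int(qrng.integers(2**31)))

    return PaperFixture(
        seed=seed, screens=screens, candidates=candidates, validated=validated,
        nfkb_library=nfkb_library, lc3_library=lc3_library,
        tn_panels=tn_panels, queries=queries, catalogs=catalogs)


def _random_query(rng: np.random.Generator, length: int = 300) -> str:
    from .seqs import random_protein
    return random_protein(rng, length)


def _library_genome_length(group_sizes, n_singletons,
                           insert_mean=30_000, insert_sd=2_000,
                           overlap=PLANTED_OVERLAP_BP, gap=1_000) -> int:
    worst_len = insert_mean + 5 * insert_sd
    spans = [worst_len + (s - 1) * (worst_len - overlap) + gap for s in group_sizes]
    return int(sum(spans) + n_singletons * (worst_len + gap) + gap)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def screen_assay(wells: pd.DataFrame, assay: str,
                 threshold: float = screening.Z_THRESHOLD,
                 toxicity_gate: float = screening.TOXICITY_GATE) -> pd.DataFrame:
    """Z-score a primary-screen well table and call hits."""
    _, zdf = screening.zscore_table(wells, assay)
    return screening.call_primary_hits(
        zdf, threshold=threshold,
        sidedness=screening.ASSAY_SIDEDNESS[assay],
        toxicity_gate=toxicity_gate)


def validate_assay(wells: pd.DataFrame, assay: str,
                   threshold: float = screening.Z_THRESHOLD,
                   min_pass: int = screening.MIN_VALIDATION_PASS) -> pd.DataFrame:
    _, zdf = screening.zscore_table(wells, assay)
    return screening.validate_hits(zdf, threshold=threshold, min_pass=min_pass)


def dereplicate_library(library: CloneLibrary,
                        min_overlap: int = dereplication.MIN_OVERLAP_BP,
                        k: int = dereplication.DEFAULT_K):
    edges = dereplication.build_overlap_graph(library.inserts, min_overlap, k)
    clone_ids = [c.clone_id for c in library.inserts]
    regions = dereplication.group_effector_regions(edges, clone_ids)
    return edges, regions, dereplication.summarize_regions(regions)


def map_panel(panel: dict, cfg: SimConfig) -> dict:
    """Locate, classify, and nominate for one transposon panel."""
    clone: CloneInsert = panel["clone"]
    orfs = tn.find_orfs(clone.sequence)
    stats = PlateStats(plate_id=f"{clone.clone_id}-ctl",
                       mean_control=cfg.null_mean, sd_control=cfg.null_sd,
                       n_controls=42)
    mutants = []
    act_cols = [c for c in panel["mutants"].columns if c.startswith("activity_")]
    for row in panel["mutants"].itertuples():
        pos, ambiguous = tn.locate_insertion(clone.sequence,
                                             panel["reads"][row.mutant_id])
        mutants.append(tn.TnMutant(
            mutant_id=row.mutant_id, insertion_pos=pos,
            activities=[getattr(row, c) for c in act_cols],
            ambiguous=ambiguous))
    tn.classify_mutant_activity(mutants, stats)
    nomination = tn.nominate_effector_genes(mutants, orfs)
    return {"clone_id": clone.clone_id, "orfs": orfs, "mutants": mutants,
            "nomination": nomination}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    assays: tuple[str, ...] = ("nfkb", "lc3", "sonar")
    z_threshold: float = screening.Z_THRESHOLD
    min_pass: int = screening.MIN_VALIDATION_PASS
    toxicity_gate: float = screening.TOXICITY_GATE
    min_overlap: int = dereplication.MIN_OVERLAP_BP
    k: int = dereplication.DEFAULT_K

    def hash(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig,
                 fixture: PaperFixture | None = None) -> RunReport:
    """Execute every stage on the planted fixture and assemble the report.

    When ``cfg.outdir`` is set, each stage's outputs are persisted as
    TSV/FASTA/GFF3/JSON so any stage can be rerun independently.
    """
    if fixture is None:
        fixture = make_paper_fixture(cfg.seed)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    provenance = [f"seed={cfg.seed}", f"config_hash={cfg.hash()}"]

    summaries: dict[str, ScreenSummary] = {}
    for assay in cfg.assays:
        hits = screen_assay(fixture.screens[assay]["primary"], assay,
                            cfg.z_threshold, cfg.toxicity_gate)
        n_assayed = int((hits.role == "clone").sum())
        primary_ids = sorted(hits.loc[hits.hit, "clone_id"])
        val = validate_assay(fixture.screens[assay]["validation"], assay,
                             cfg.z_threshold, cfg.min_pass)
        n_validated = int(val.validated.sum())
        summaries[assay] = screening.summarize_screen(
            assay, n_assayed, len(primary_ids), n_validated)
        if outdir:
            write_tsv(hits, outdir / f"{assay}_primary_hits.tsv", provenance)
            write_tsv(val, outdir / f"{assay}_validation.tsv", provenance)

    region_summaries = {}
    for assay, library in (("nfkb", fixture.nfkb_library),
                           ("lc3", fixture.lc3_library)):
        edges, regions, summary = dereplicate_library(library, cfg.min_overlap, cfg.k)
        region_summaries[assay] = summary
        if outdir:
            write_fasta(outdir / f"{assay}_inserts.fasta",
                        {c.clone_id: c.sequence for c in library.inserts})
            write_tsv(pd.DataFrame([vars(e) for e in edges]),
                      outdir / f"{assay}_overlap_edges.tsv", provenance)
            write_tsv(pd.DataFrame(
                [(r.region_id, m, r.is_singleton)
                 for r in regions for m in sorted(r.members)],
                columns=["region_id", "clone_id", "is_singleton"]),
                outdir / f"{assay}_regions.tsv", provenance)

    nfkb_cfg = SimConfig(seed=cfg.seed, **ASSAY_CONFIGS["nfkb"])
    nominations = []
    for panel in fixture.tn_panels:
        result = map_panel(panel, nfkb_cfg)
        nom = result["nomination"]
        nominations.append({
            "clone_id": result["clone_id"],
            "candidate_genes": nom.candidate_genes,
            "inactivating_counts": nom.inactivating_counts,
            "tolerated_counts": nom.tolerated_counts,
            "n_intergenic_inactivating": nom.n_intergenic_inactivating,
            "unambiguous": nom.unambiguous,
        })
        if outdir:
            (outdir / f"{result['clone_id']}_orfs.gff3").write_text(
                tn.orfs_to_gff3(result["orfs"], result["clone_id"]))
            write_tsv(pd.DataFrame(
                [(m.mutant_id, m.insertion_pos, m.inactive, m.ambiguous)
                 for m in result["mutants"]],
                columns=["mutant_id", "insertion_pos", "inactive", "ambiguous"]),
                outdir / f"{result['clone_id']}_mutants.tsv", provenance)

    prev = prevalence.compute_prevalence(fixture.queries, fixture.catalogs)

    report = RunReport(
        seed=cfg.seed, config_hash=cfg.hash(),
        screen_summaries=summaries, region_summaries=region_summaries,
        nominations=nominations, prevalence=prev)
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    return report
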