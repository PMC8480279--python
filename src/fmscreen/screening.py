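"""Per-plate Z-score normalization, toxicity gating, and hit calling.

Every readout is normalized to the empty-vector control wells of its own
plate: Z = (readout - mean_control) / sd_control, with the control mean and
sample SD (n-1 denominator) computed from that plate's non-failed control
wells only. A clone is a primary hit when Z exceeds the threshold (upper
tail for the GFP and puncta assays, either tail for the ratiometric redox
assay), its well passed QC, and its dead-cell fraction is below the
toxicity gate. Primary hits are validated when at least ``min_pass`` of the
replicate wells again show Z strictly above the threshold.

Well tables are pandas DataFrames with one row per well; ``WellRecord``
documents the row schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

Z_THRESHOLD = 3.0
MIN_VALIDATION_PASS = 3
VALIDATION_REPLICATES = 4
TOXICITY_GATE = 0.5

#: default sidedness of the hit call per assay; the redox sensor reports
#: deviations in either direction as activity
ASSAY_SIDEDNESS = {"nfkb": "upper", "lc3": "upper", "sonar": "two_sided"}


@dataclass
class WellRecord:
    """Schema of one well-table row."""

    plate_id: str
    row: str
    col: int
    role: str  # "clone" | "control"
    clone_id: str | None
    replicate: int
    readout: float | None
    f420: float | None = None
    f485: float | None = None
    death_fraction: float | None = None
    qc_failed: bool = False


@dataclass
class PlateStats:
    """Control summary used to convert one plate's readouts to Z-scores."""

    plate_id: str
    mean_control: float
    sd_control: float
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need >= 2 control wells for plate statistics")
        if not self.sd_control > 0:
            raise ValueError("sd_control must be positive")


@dataclass
class ScreenSummary:
    assay: str
    n_assayed: int
    n_primary_hits: int
    primary_rate_pct: float | None
    n_validated: int
    validated_rate_pct: float | None


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero — the convention behind the printed rates."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, denom: int, ndigits: int = 1) -> float | None:
    """100*count/denom rounded half away from zero; None when denom == 0."""
    if denom == 0:
        return None
    return round_half_away(100.0 * count / denom, ndigits)


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def compute_well_readout(rec: dict | pd.Series, assay: str) -> tuple[float | None, bool]:
    """(readout, qc_failed) for one well.

    The redox assay derives its readout as the channel ratio f420/f485; a
    zero denominator is a QC failure, not a number. The image-derived
    assays pass their readout through.
    """
    if assay == "sonar":
        f420, f485 = rec["f420"], rec["f485"]
        if f485 is None or f485 == 0 or pd.isna(f485):
            return None, True
        return f420 / f485, bool(rec.get("qc_failed", False))
    return rec["readout"], bool(rec.get("qc_failed", False))


def add_readouts(wells: pd.DataFrame, assay: str) -> pd.DataFrame:
    """Vectorized ``compute_well_readout`` over a well table."""
    df = wells.copy()
    if assay == "sonar":
        bad = df["f485"].isna() | (df["f485"] == 0)
        df.loc[bad, "qc_failed"] = True
        with np.errstate(divide="ignore", invalid="ignore"):
            df["readout"] = np.where(bad, np.nan, df["f420"] / df["f485"])
    return df


# ---------------------------------------------------------------------------
# Z-scores
# ---------------------------------------------------------------------------

def compute_plate_zscores(wells: pd.DataFrame) -> tuple[PlateStats, pd.DataFrame]:
    """Z-scores for one plate of one replicate.

    Control statistics use the plate's usable (non-QC-failed) control wells
    only; every clone well gets z = (readout - mean_control) / sd_control.
    QC-failed wells get no Z. Raises ValueError when fewer than two usable
    controls remain.
    """
    plate_ids = wells["plate_id"].unique()
    if len(plate_ids) != 1:
        raise ValueError("compute_plate_zscores expects wells from a single plate")
    ctl = wells[(wells.role == "control") & ~wells.qc_failed & wells.readout.notna()]
    if len(ctl) < 2:
        raise ValueError(
            f"plate {plate_ids[0]}: fewer than 2 usable control wells; plate rejected")
    mean_c = float(ctl.readout.mean())
    sd_c = float(ctl.readout.std(ddof=1))
    stats = PlateStats(str(plate_ids[0]), mean_c, sd_c, len(ctl))
    df = wells.copy()
    df["z"] = np.where(df.qc_failed | df.readout.isna(), np.nan,
                       (df.readout - mean_c) / sd_c)
    return stats, df


def zscore_table(wells: pd.DataFrame, assay: str) -> tuple[list[PlateStats], pd.DataFrame]:
    """Readout derivation plus per-(plate, replicate) Z-scoring."""
    df = add_readouts(wells, assay)
    stats, parts = [], []
    for _, grp in df.groupby(["plate_id", "replicate"], sort=True):
        st, z = compute_plate_zscores(grp)
        stats.append(st)
        parts.append(z)
    out = pd.concat(parts, ignore_index=True) if parts else df.assign(z=np.nan)
    return stats, out


# ---------------------------------------------------------------------------
# hit calling and validation
# ---------------------------------------------------------------------------

def call_primary_hits(
    zscores: pd.DataFrame,
    threshold: float = Z_THRESHOLD,
    sidedness: str = "upper",
    toxicity_gate: float = TOXICITY_GATE,
) -> pd.DataFrame:
    """Flag clone wells as primary hits.

    hit <=> z > threshold (or |z| > threshold for two_sided), the well is
    not QC-failed, and death_fraction <= toxicity_gate. Wells that clear
    the Z threshold but fail the toxicity gate are reported with
    ``gated_toxic=True`` rather than dropped.
    """
    if sidedness not in ("upper", "two_sided"):
        raise ValueError("sidedness must be 'upper' or 'two_sided'")
    df = zscores[zscores.role == "clone"].copy()
    zval = df.z.to_numpy()
    exceeds = np.abs(zval) > threshold if sidedness == "two_sided" else zval > threshold
    exceeds &= ~df.qc_failed.to_numpy() & ~np.isnan(zval)
    toxic = df.death_fraction.to_numpy() > toxicity_gate
    df["gated_toxic"] = exceeds & toxic
    df["hit"] = exceeds & ~toxic
    return df


def validate_hits(
    replicate_z: pd.DataFrame,
    threshold: float = Z_THRESHOLD,
    min_pass: int = MIN_VALIDATION_PASS,
    n_replicates: int = VALIDATION_REPLICATES,
) -> pd.DataFrame:
    """Apply the 3-of-4 replicate rule to candidate clones.

    A candidate validates when at least ``min_pass`` of its ``n_replicates``
    wells show Z strictly above ``threshold``. Candidates with missing
    replicates are flagged incomplete and not validated.
    """
    df = replicate_z[replicate_z.role == "clone"]
    rows = []
    for cid, grp in df.groupby("clone_id", sort=True):
        n_rep = grp.replicate.nunique()
        n_pass = int((grp.z > threshold).sum())
        incomplete = n_rep < n_replicates
        rows.append((cid, n_rep, n_pass, incomplete,
                     (not incomplete) and n_pass >= min_pass))
    return pd.DataFrame(rows, columns=["clone_id", "n_replicates", "n_pass",
                                       "incomplete", "validated"])


def summarize_screen(assay: str, n_assayed: int, n_primary_hits: int,
                     n_validated: int) -> ScreenSummary:
    """Primary and validated hit rates as printed percentages.

    The primary rate is relative to the number of clones assayed; the
    validated rate is relative to the primary-hit count. Percentages are
    rounded half away from zero to one decimal.
    """
    if not n_validated <= n_primary_hits <= n_assayed:
        raise ValueError("expected n_validated <= n_primary_hits <= n_assayed")
    return ScreenSummary(
        assay=assay,
        n_assayed=n_assayed,
        n_primary_hits=n_primary_hits,
        primary_rate_pct=percent(n_primary_hits, n_assayed),
        n_validated=n_validated,
        validated_rate_pct=percent(n_validated, n_primary_hits),
    )
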