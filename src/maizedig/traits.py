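"""Derived agronomic traits and histological tissue synthesis.

Cross-sections of the internode below the main ear are FASGA-stained
(lignified tissue red, low-lignified blue) and segmented into 44 named
zones whose raw pixel counts partition the section.  Counts are turned
into %ICS (percentage of the internode cross-section) and grouped into
synthetic tissue traits — colour groups per compartment (pith / dark
rind / light rind / bundle) and digestibility classes of the medullary
region — plus rind totals and DRT/LRT-to-rind ratios.

Agronomic side: digestible yield (t digestible DM/ha) as
``yield × DM digestibility / 100`` computed at block level and averaged
upward, and percent change between condition means.
"""

from __future__ import annotations

from types import MappingProxyType

import numpy as np
import pandas as pd

__all__ = [
    "ZONES",
    "SYNTHETIC_GROUPS",
    "percent_ics",
    "synthesize_tissue_traits",
    "digestible_yield",
    "percent_change",
    "derive_trial_traits",
    "segmentation_traits",
    "long_to_wide",
    "wide_to_long",
]

# The 44 segmentation zones.  Medullary (MT), dark/light rind (DRT/LRT)
# and bundle (BT) names follow the segmentation plugin; the epidermis
# subzones are registered as ET1-ET11 placeholders (only MT/DRT/LRT/BT
# zones enter synthetic traits).  Data-driven: edit here, not in code.
ZONES: tuple[str, ...] = tuple(
    ["MT1a", "MT1b", "MT2", "MT2a", "MT2b", "MT4a", "MT4b", "MT5", "MT5a", "MT5b"]
    + [f"DRT{i}" for i in range(1, 10)]
    + [f"LRT{i}" for i in range(1, 10)]
    + [f"BT{i}" for i in range(1, 6)]
    + [f"ET{i}" for i in range(1, 12)]
)

# Synthetic trait memberships: FASGA colour per compartment, and
# digestibility classes of the medullary region.
SYNTHETIC_GROUPS = MappingProxyType(
    {
        "blue_pith": ("MT2", "MT5"),
        "blue_drt": ("DRT1", "DRT3", "DRT6"),
        "blue_lrt": ("LRT1", "LRT3", "LRT6"),
        "blue_bundle": ("BT2", "BT5"),
        "red_drt": ("DRT2", "DRT4", "DRT5", "DRT7", "DRT8", "DRT9"),
        "red_lrt": ("LRT2", "LRT4", "LRT5", "LRT7", "LRT8", "LRT9"),
        "red_bundle": ("BT1", "BT3", "BT4"),
        "highly_digestible": ("MT2b", "MT5b"),
        "digestible": ("MT2a", "MT5a"),
        "highly_indigestible": ("MT1a", "MT4a"),
        "indigestible": ("MT1b", "MT4b"),
    }
)


def percent_ics(counts, total: int | float | None = None) -> dict[str, float]:
    """Zone pixel counts → %ICS (share of the internode cross-section).

    *counts* maps zone name to pixel count; *total* defaults to the sum
    of counts (zones partition the section).  Each zone becomes
    ``count * 100 / total``; over a full partition the values sum to 100.
    """
    counts = dict(counts)
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise ValueError("total cross-section pixel count must be > 0")
    out = {}
    for zone, c in counts.items():
        if c < 0:
            raise ValueError(f"negative pixel count for zone {zone}")
        if c > total:
            raise ValueError(f"zone {zone} count {c} exceeds total {total}")
        out[zone] = c * 100.0 / total
    return out


def synthesize_tissue_traits(
    percents, groups=SYNTHETIC_GROUPS
) -> dict[str, float]:
    """Sum member-zone %ICS into synthetic tissue traits.

    Adds compartment totals (``drt_total`` = blue + red dark rind,
    ``lrt_total`` likewise, ``rind_total`` = both) and the
    ``drt_to_rind`` / ``lrt_to_rind`` ratios.
    """
    out: dict[str, float] = {}
    for trait, members in groups.items():
        missing = [z for z in members if z not in percents]
        if missing:
            raise KeyError(f"trait {trait!r} missing member zones {missing}")
        out[trait] = float(sum(percents[z] for z in members))
    out["drt_total"] = out["blue_drt"] + out["red_drt"]
    out["lrt_total"] = out["blue_lrt"] + out["red_lrt"]
    out["rind_total"] = out["drt_total"] + out["lrt_total"]
    if out["rind_total"] > 0:
        out["drt_to_rind"] = out["drt_total"] / out["rind_total"]
        out["lrt_to_rind"] = out["lrt_total"] / out["rind_total"]
    else:
        out["drt_to_rind"] = out["lrt_to_rind"] = float("nan")
    return out


def digestible_yield(yield_t_ha: float, dm_digestibility_pct: float) -> float:
    """Digestible yield, t digestible DM/ha = yield × DM digestibility / 100."""
    if yield_t_ha < 0:
        raise ValueError("yield must be >= 0")
    if not 0 <= dm_digestibility_pct <= 100:
        raise ValueError("DM digestibility must be in [0, 100] %")
    return yield_t_ha * dm_digestibility_pct / 100.0


def percent_change(reference: float, value: float) -> float:
    """Decline of *value* relative to *reference*, in percent."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return (reference - value) / reference * 100.0


def derive_trial_traits(wide: pd.DataFrame) -> pd.DataFrame:
    """Add block-level derived traits to a wide trial table.

    Currently: ``digestible_yield`` from ``yield`` and
    ``dm_digestibility``.  Computed per record (block level) so that
    upward averaging matches the trial's aggregation order; rows with
    either input missing get an explicit null.
    """
    out = wide.copy()
    if "yield" in out.columns and "dm_digestibility" in out.columns:
        y = out["yield"]
        d = out["dm_digestibility"]
        bad = ((y < 0) | (d < 0) | (d > 100)) & y.notna() & d.notna()
        if bad.any():
            raise ValueError("yield/digestibility out of range in trial table")
        out["digestible_yield"] = y * d / 100.0
    return out


def segmentation_traits(seg: pd.DataFrame, id_cols=("sample",)) -> pd.DataFrame:
    """Per-sample %ICS and synthetic traits from a zone-count table.

    *seg* holds one row per cross-section with zone columns and a
    ``total_px`` column; returns the id columns plus every synthetic
    trait and ratio.
    """
    zone_cols = [c for c in seg.columns if c in ZONES]
    if not zone_cols:
        raise ValueError("no recognised zone columns in segmentation table")
    rows = []
    for _, row in seg.iterrows():
        total = row["total_px"] if "total_px" in seg.columns else None
        pct = percent_ics({z: row[z] for z in zone_cols}, total)
        rec = {c: row[c] for c in id_cols if c in seg.columns}
        rec.update(synthesize_tissue_traits(pct))
        rows.append(rec)
    return pd.DataFrame(rows)


DESIGN_COLS = ["year", "site", "condition", "hybrid", "block", "row", "col"]


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Tidy long trial table (trait, value columns) → one column per trait."""
    idx = [c for c in DESIGN_COLS if c in long.columns]
    wide = long.pivot_table(
        index=idx, columns="trait", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


def wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    idx = [c for c in DESIGN_COLS if c in wide.columns]
    traits = [c for c in wide.columns if c not in idx]
    return wide.melt(id_vars=idx, value_vars=traits, var_name="trait", value_name="value")
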