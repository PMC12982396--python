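"""Hierarchical basophil gating and reverse gating.

Forward hierarchy: singlets (FSC_H/FSC_A ratio band) -> CD45+ leukocytes ->
CD123+ HLA-DRneg basophils -> CD63++ activated basophils. Reverse gating
applies the marker gates to ALL events first and then splits the
marker-positive events by the same scatter band, which counts the putative
basophils whose scatter characteristics were altered by strong activation
and would otherwise silently leave the basophil gate.

All gate boundaries are closed intervals; events with FSC_A <= 0 are dropped
before the ratio computation and reported in the diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import CHANNELS

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = CHANNELS


class GatingError(ValueError):
    """Raised on invalid event tables or gate configurations."""


@dataclass(frozen=True)
class GateConfig:
    """Gate geometry and marker thresholds.

    ``singlet_band_width`` is the relative half-width w of the accepted
    FSC_H/FSC_A ratio around its robust (median) center: an event is a
    singlet iff ratio in [center*(1-w), center*(1+w)]. Marker thresholds are
    fixed numbers by default; ``threshold_mode="auto_valley"`` re-derives the
    CD45 and CD63 thresholds per sample from the valley of a kernel density
    estimate between the two dominant intensity modes (CD123/HLA-DR gates
    bound a rare population, where a valley estimate is unreliable, and stay
    fixed).
    """

    singlet_band_width: float = 0.15
    cd45_min: float = 800.0
    cd123_min: float = 500.0
    hladr_max: float = 300.0
    cd63_min: float = 800.0
    threshold_mode: str = "fixed"

    def __post_init__(self) -> None:
        if not (0.0 < self.singlet_band_width < 1.0):
            raise GatingError("singlet_band_width: must lie in (0, 1)")
        for name in ("cd45_min", "cd123_min", "hladr_max", "cd63_min"):
            if getattr(self, name) < 0:
                raise GatingError(f"{name}: must be >= 0")
        if self.threshold_mode not in ("fixed", "auto_valley"):
            raise GatingError("threshold_mode: must be 'fixed' or 'auto_valley'")


def default_gate_config() -> GateConfig:
    """Thresholds matched to the synthetic generator's channel model."""
    return GateConfig()


@dataclass(frozen=True)
class PopulationCounts:
    """Event counts of one sample's gated populations.

    ``n_basophil_altered`` counts marker-positive events outside the singlet
    band (reverse gating); everything else follows the forward hierarchy.
    """

    n_total: int = 0
    n_singlets: int = 0
    n_cd45: int = 0
    n_basophil_intact: int = 0
    n_basophil_altered: int = 0
    n_cd63pos: int = 0
    n_fsc_zero_dropped: int = 0
    donor_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("n_total", "n_singlets", "n_cd45", "n_basophil_intact",
                     "n_basophil_altered", "n_cd63pos", "n_fsc_zero_dropped"):
            if getattr(self, name) < 0:
                raise GatingError(f"{name}: must be >= 0")
        if not (self.n_total >= self.n_singlets >= self.n_cd45
                >= self.n_basophil_intact >= self.n_cd63pos):
            raise GatingError("population counts violate the gate-nesting invariant")

    def _frac(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def frac_basophil(self) -> float:
        """Intact basophils as a fraction of CD45+ leukocytes (b). NaN if undefined."""
        return self._frac(self.n_basophil_intact, self.n_cd45)

    @property
    def frac_cd63pos(self) -> float:
        """CD63++ basophils as a fraction of CD45+ leukocytes (c)."""
        return self._frac(self.n_cd63pos, self.n_cd45)

    @property
    def frac_cd63pos_of_basophils(self) -> float:
        """CD63++ fraction of intact basophils (the clinical BAT readout)."""
        return self._frac(self.n_cd63pos, self.n_basophil_intact)

    @property
    def frac_altered_of_putative(self) -> float:
        """Altered-scatter share of all putative (intact + altered) basophils."""
        return self._frac(self.n_basophil_altered,
                          self.n_basophil_altered + self.n_basophil_intact)

    def to_dict(self) -> dict:
        return {
            "donor_id": self.donor_id,
            "condition": self.condition,
            "n_total": self.n_total,
            "n_singlets": self.n_singlets,
            "n_cd45": self.n_cd45,
            "n_basophil_intact": self.n_basophil_intact,
            "n_basophil_altered": self.n_basophil_altered,
            "n_cd63pos": self.n_cd63pos,
            "n_fsc_zero_dropped": self.n_fsc_zero_dropped,
        }


def _validate_events(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise GatingError(f"event table is missing required columns: {missing}")


def _ratio_and_valid(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """FSC_H/FSC_A ratio and the FSC_A > 0 validity mask."""
    fsc_a = events["FSC_A"].to_numpy(dtype=float)
    fsc_h = events["FSC_H"].to_numpy(dtype=float)
    valid = fsc_a > 0
    ratio = np.zeros(len(fsc_a))
    np.divide(fsc_h, fsc_a, out=ratio, where=valid)
    return ratio, valid


def _band_mask(ratio: np.ndarray, valid: np.ndarray, width: float) -> np.ndarray:
    if not valid.any():
        return np.zeros_like(valid)
    center = float(np.median(ratio[valid]))
    lo, hi = center * (1.0 - width), center * (1.0 + width)
    return valid & (ratio >= lo) & (ratio <= hi)


def gate_singlets(events: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    """Boolean mask of events inside the FSC_H/FSC_A singlet band.

    The band center is the median ratio of all FSC_A > 0 events; the closed
    interval [center*(1-w), center*(1+w)] is kept. FSC_A <= 0 events are
    excluded and logged.
    """
    _validate_events(events)
    if len(events) == 0:
        raise GatingError("event table is empty")
    ratio, valid = _ratio_and_valid(events)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("gate_singlets: dropped %d events with FSC_A <= 0", n_dropped)
    return _band_mask(ratio, valid, cfg.singlet_band_width)


def gate_leukocytes(events: pd.DataFrame, mask: np.ndarray,
                    cfg: GateConfig) -> np.ndarray:
    """CD45+ events within the parent mask (SSC is diagnostics-only)."""
    _validate_events(events)
    cd45_min = _resolve_threshold(events, mask, "CD45", cfg.cd45_min, cfg)
    return mask & (events["CD45"].to_numpy(dtype=float) >= cd45_min)


def gate_basophils(events: pd.DataFrame, mask: np.ndarray,
                   cfg: GateConfig) -> np.ndarray:
    """CD123+ HLA-DRneg events within the parent (leukocyte) mask."""
    _validate_events(events)
    cd123 = events["CD123"].to_numpy(dtype=float)
    hladr = events["HLA_DR"].to_numpy(dtype=float)
    return mask & (cd123 >= cfg.cd123_min) & (hladr <= cfg.hladr_max)


def gate_cd63pos(events: pd.DataFrame, mask: np.ndarray,
                 cfg: GateConfig) -> np.ndarray:
    """CD63++ events within the parent (basophil) mask."""
    _validate_events(events)
    cd63_min = _resolve_threshold(events, mask, "CD63", cfg.cd63_min, cfg)
    return mask & (events["CD63"].to_numpy(dtype=float) >= cd63_min)


def _resolve_threshold(events: pd.DataFrame, mask: np.ndarray, channel: str,
                       fixed: float, cfg: GateConfig) -> float:
    if cfg.threshold_mode != "auto_valley":
        return fixed
    values = events.loc[np.asarray(mask, dtype=bool), channel].to_numpy(dtype=float)
    try:
        return valley_threshold(values)
    except GatingError:
        logger.warning("auto_valley on %s failed; falling back to fixed "
                       "threshold %.1f", channel, fixed)
        return fixed


def valley_threshold(values: np.ndarray, grid_size: int = 512) -> float:
    """Threshold at the KDE valley between the two dominant intensity modes.

    Works on log10 intensities (positive values only). Raises
    :class:`GatingError` when fewer than two modes are found.
    """
    from scipy.signal import argrelextrema
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    values = values[values > 0]
    if values.size < 50:
        raise GatingError("auto_valley: too few events")
    logv = np.log10(values)
    kde = gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), grid_size)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if maxima.size < 2:
        raise GatingError("auto_valley: fewer than two density modes")
    top2 = np.sort(maxima[np.argsort(dens[maxima])[-2:]])
    valley = top2[0] + int(np.argmin(dens[top2[0]:top2[1] + 1]))
    return float(10 ** grid[valley])


def reverse_gate_altered_scatter(
    events: pd.DataFrame, cfg: GateConfig
) -> tuple[int, int]:
    """Count intact vs altered-scatter putative basophils.

    Marker gates (CD45+, CD123+, HLA-DRneg) are applied to ALL events without
    a singlet pre-gate; the marker-positive events are then split by the
    singlet ratio band: inside = intact, outside = altered. Returns
    ``(n_intact, n_altered)``. The intact count equals the forward-gated
    basophil count for the same thresholds, since the gates commute.
    """
    _validate_events(events)
    if len(events) == 0:
        return 0, 0
    ratio, valid = _ratio_and_valid(events)
    markers = valid.copy()
    markers = gate_leukocytes(events, markers, cfg)
    markers = gate_basophils(events, markers, cfg)
    if not markers.any():
        return 0, 0
    band = _band_mask(ratio, valid, cfg.singlet_band_width)
    n_intact = int((markers & band).sum())
    n_altered = int((markers & ~band).sum())
    return n_intact, n_altered


def count_populations(events: pd.DataFrame, cfg: GateConfig) -> PopulationCounts:
    """Run the full forward hierarchy plus reverse gating on one sample."""
    if len(events) == 0:
        return PopulationCounts()
    _validate_events(events)
    _, valid = _ratio_and_valid(events)
    singlets = gate_singlets(events, cfg)
    cd45 = gate_leukocytes(events, singlets, cfg)
    basophils = gate_basophils(events, cd45, cfg)
    cd63 = gate_cd63pos(events, basophils, cfg)
    n_intact_rev, n_altered = reverse_gate_altered_scatter(events, cfg)
    donor_id = str(events["donor_id"].iloc[0]) if "donor_id" in events else ""
    condition = str(events["condition"].iloc[0]) if "condition" in events else ""
    return PopulationCounts(
        n_total=len(events),
        n_singlets=int(singlets.sum()),
        n_cd45=int(cd45.sum()),
        n_basophil_intact=int(basophils.sum()),
        n_basophil_altered=n_altered,
        n_cd63pos=int(cd63.sum()),
        n_fsc_zero_dropped=int((~valid).sum()),
        donor_id=donor_id,
        condition=condition,
    )


def counts_table(counts: Sequence[PopulationCounts]) -> pd.DataFrame:
    """Tidy per-sample counts table (one row per sample)."""
    return pd.DataFrame([c.to_dict() for c in counts])
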