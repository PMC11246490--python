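"""Shared containers for split-panel mass-cytometry screens.

A split-panel screen stains aliquots of one cell pool with K different
antibody panels.  Every panel carries the same conserved (core) markers,
so cells from different panels can be aligned in conserved-marker space,
while each panel adds its own disjoint set of screen markers that are
therefore measured on only a subset of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CytoStitchError",
    "ConfigurationError",
    "InputError",
    "ParameterError",
    "InsufficientDataError",
    "PanelDesign",
    "ExpressionTable",
]

META_COLUMNS = ("donor_id", "panel_id")


class CytoStitchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CytoStitchError):
    """Invalid configuration (bad simplex, missing marker model, bad gate...)."""


class InputError(CytoStitchError):
    """Invalid or inconsistent input data."""


class ParameterError(CytoStitchError):
    """Parameter outside its admissible range for the given data."""


class InsufficientDataError(CytoStitchError):
    """Not enough observations to perform the requested computation."""


@dataclass(frozen=True)
class PanelDesign:
    """Which markers are conserved vs. panel-specific across staining panels.

    Parameters
    ----------
    conserved_markers
        Markers stained on every panel (the alignment core).
    panels
        Mapping panel_id -> screen markers unique to that panel.  Screen
        marker lists must be pairwise disjoint and disjoint from the
        conserved set: each screen target is measured on exactly one panel.
    """

    conserved_markers: tuple[str, ...]
    panels: Mapping[str, tuple[str, ...]]

    def __init__(
        self,
        conserved_markers: Sequence[str],
        panels: Mapping[str, Sequence[str]],
    ) -> None:
        object.__setattr__(self, "conserved_markers", tuple(conserved_markers))
        object.__setattr__(
            self, "panels", {str(p): tuple(m) for p, m in panels.items()}
        )
        self._validate()

    def _validate(self) -> None:
        if not self.conserved_markers:
            raise ConfigurationError("conserved marker list must be non-empty")
        if len(set(self.conserved_markers)) != len(self.conserved_markers):
            raise ConfigurationError("duplicate conserved marker names")
        conserved = set(self.conserved_markers)
        seen: set[str] = set()
        for pid, screen in self.panels.items():
            smset = set(screen)
            if len(smset) != len(screen):
                raise ConfigurationError(f"duplicate screen markers in panel {pid!r}")
            if smset & conserved:
                raise ConfigurationError(
                    f"panel {pid!r} screen markers overlap the conserved set: "
                    f"{sorted(smset & conserved)}"
                )
            if smset & seen:
                raise ConfigurationError(
                    f"screen markers shared between panels: {sorted(smset & seen)}"
                )
            seen |= smset

    @property
    def panel_ids(self) -> tuple[str, ...]:
        return tuple(self.panels)

    @property
    def screen_markers(self) -> tuple[str, ...]:
        out: list[str] = []
        for screen in self.panels.values():
            out.extend(screen)
        return tuple(out)

    @property
    def all_markers(self) -> tuple[str, ...]:
        return self.conserved_markers + self.screen_markers

    def markers_for(self, panel_id: str) -> tuple[str, ...]:
        """All markers measured on cells stained with ``panel_id``."""
        return self.conserved_markers + tuple(self.panels[panel_id])

    def panel_of(self, marker: str) -> str | None:
        """Owning panel for a screen marker; ``None`` for conserved markers."""
        for pid, screen in self.panels.items():
            if marker in screen:
                return pid
        return None

    def to_dict(self) -> dict:
        return {
            "conserved_markers": list(self.conserved_markers),
            "panels": {p: list(m) for p, m in self.panels.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PanelDesign":
        return cls(d["conserved_markers"], d["panels"])


@dataclass
class ExpressionTable:
    """Per-cell marker expression with donor/panel annotations.

    ``data`` is indexed by unique ``cell_id`` and contains the metadata
    columns ``donor_id`` and ``panel_id`` followed by one column per marker
    on the asinh scale.  Unmeasured entries (screen markers off the cell's
    panel) are NaN; the boolean measured mask is derived from the design.
    """

    data: pd.DataFrame
    panel_design: PanelDesign
    _mask: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def markers(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def measured_mask(self) -> pd.DataFrame:
        """Cell x marker boolean mask implied by the panel design."""
        if self._mask is None:
            design = self.panel_design
            panel_ids = self.data["panel_id"].to_numpy()
            mask = pd.DataFrame(
                True, index=self.data.index, columns=self.markers, dtype=bool
            )
            for marker in self.markers:
                owner = design.panel_of(marker)
                if owner is not None:
                    mask[marker] = panel_ids == owner
            self._mask = mask
        return self._mask

    def validate(self) -> None:
        df = self.data
        for col in META_COLUMNS:
            if col not in df.columns:
                raise InputError(f"missing required column {col!r}")
        if not df.index.is_unique:
            raise InputError("cell_id index must be unique")
        design = self.panel_design
        known = set(design.all_markers)
        unknown = [m for m in self.markers if m not in known]
        if unknown:
            raise InputError(f"marker columns not in panel design: {unknown}")
        bad_panels = set(df["panel_id"].unique()) - set(design.panel_ids)
        if bad_panels:
            raise InputError(f"unknown panel ids: {sorted(bad_panels)}")
        self._mask = None
        values = df[self.markers]
        mask = self.measured_mask
        measured = values.to_numpy()[mask.to_numpy()]
        if measured.size and not np.all(np.isfinite(measured)):
            raise InputError("measured values must be finite")
        if measured.size and np.any(measured < 0):
            raise InputError("measured values must be >= 0 (asinh scale)")
        stray = values.notna().to_numpy() & ~mask.to_numpy()
        if stray.any():
            i, j = np.argwhere(stray)[0]
            raise InputError(
                f"value present for unmeasured entry (cell {df.index[i]!r}, "
                f"marker {self.markers[j]!r})"
            )
        missing = values.isna().to_numpy() & mask.to_numpy()
        if missing.any():
            i, j = np.argwhere(missing)[0]
            raise InputError(
                f"NaN in a measured entry (cell {df.index[i]!r}, "
                f"marker {self.markers[j]!r})"
            )

    def marker_values(self, marker: str) -> pd.Series:
        """Measured values for one marker (off-panel cells dropped)."""
        return self.data[marker].dropna()

    def subset(self, cell_ids) -> "ExpressionTable":
        return ExpressionTable(self.data.loc[cell_ids], self.panel_design)

    def copy_with(self, data: pd.DataFrame) -> "ExpressionTable":
        return ExpressionTable(data, self.panel_design)
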