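"""Canonical data model for the 21-mediator longitudinal serum panel.

The study design is cross-sectional ("destructive sampling"): each animal is
bled at exactly one time point, so a panel is a long table of
(subject, procedure, time, mediator, concentration) records rather than a set
of per-animal trajectories.  Procedures are UNTREATED (baseline, time 0 only),
ST (surgical cannulation trauma) and ST_HS (the same trauma plus controlled
hemorrhagic shock), each observed at 1–4 h.

Concentrations are pg/ml for the 20 cytokines/chemokines and a µM-equivalent
scale for the nitric-oxide reaction products NO2-/NO3-; no unit conversion is
performed because every scale-sensitive analysis normalizes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, PanelFormatError, PanelIntegrityError

#: The three experimental arms.  UNTREATED exists only at time 0.
PROCEDURES = ("UNTREATED", "ST", "ST_HS")

#: Canonical vocabulary for the 21 serum analytes (20 cytokines/chemokines
#: from the multiplex bead panel plus NO2-/NO3-).  "IL-12.total" is the
#: canonical token for total IL-12 (p40/p70).
MEDIATORS = (
    "bFGF",
    "GM-CSF",
    "IFN-g",
    "IL-1a",
    "IL-1b",
    "IL-2",
    "IL-4",
    "IL-5",
    "IL-6",
    "IL-10",
    "IL-12.total",
    "IL-13",
    "IL-17",
    "IP-10",
    "KC",
    "MCP-1",
    "MIG",
    "MIP-1a",
    "TNF-a",
    "VEGF",
    "NO2-/NO3-",
)

#: Synonyms seen in the literature / instrument exports, mapped to canonical.
DEFAULT_ALIASES: dict[str, str] = {
    "IL-12p40/p70": "IL-12.total",
    "IL-12 p40/p70": "IL-12.total",
    "p40/p75": "IL-12.total",
    "IL-12": "IL-12.total",
    "IFN-gamma": "IFN-g",
    "IFNg": "IFN-g",
    "IL-1alpha": "IL-1a",
    "IL-1beta": "IL-1b",
    "MIP-1alpha": "MIP-1a",
    "TNF-alpha": "TNF-a",
    "TNFa": "TNF-a",
    "NO2/NO3": "NO2-/NO3-",
    "NO2-/NO3- (uM)": "NO2-/NO3-",
}

TIMES = (0, 1, 2, 3, 4)
TREATED_TIMES = (1, 2, 3, 4)

REQUIRED_COLUMNS = ("subject_id", "procedure", "time_h", "mediator", "value")


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``severity`` is 'error' or 'warning'."""

    severity: str
    code: str
    message: str


@dataclass
class MediatorPanel:
    """Long-format panel of per-animal mediator concentrations.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id, procedure, time_h, mediator,
        value``; one row per (subject, mediator).
    mediators
        Ordered mediator vocabulary for this panel (defaults to the analytes
        present, in canonical order).
    """

    data: pd.DataFrame
    mediators: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelFormatError(f"missing required columns: {missing}")
        if not self.mediators:
            present = self.data["mediator"].unique().tolist()
            canon = [m for m in MEDIATORS if m in present]
            extra = [m for m in present if m not in MEDIATORS]
            self.mediators = tuple(canon + sorted(extra))

    # -- structure -------------------------------------------------------

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject with its (procedure, time_h)."""
        return (
            self.data[["subject_id", "procedure", "time_h"]]
            .drop_duplicates()
            .set_index("subject_id")
        )

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def design(self) -> pd.DataFrame:
        """Subject counts per (procedure, time_h) cell."""
        return (
            self.subjects.reset_index()
            .groupby(["procedure", "time_h"], observed=True)["subject_id"]
            .nunique()
            .rename("n")
            .reset_index()
        )

    def wide(
        self,
        procedure: str | Sequence[str] | None = None,
        times: Iterable[int] | None = None,
    ) -> pd.DataFrame:
        """Subject × mediator matrix, optionally restricted by arm and time.

        The index is subject_id; ``procedure`` and ``time_h`` are carried as
        extra columns in front of the mediator columns.  Row order is
        (time_h, subject_id) for determinism.
        """
        df = self.data
        if procedure is not None:
            procs = [procedure] if isinstance(procedure, str) else list(procedure)
            df = df[df["procedure"].isin(procs)]
        if times is not None:
            df = df[df["time_h"].isin(list(times))]
        if df.empty:
            raise PanelIntegrityError(
                f"no samples for procedure={procedure!r}, times={times!r}"
            )
        w = df.pivot_table(
            index=["time_h", "subject_id", "procedure"],
            columns="mediator",
            values="value",
            aggfunc="first",
            observed=True,
        ).reset_index()
        w = w.sort_values(["time_h", "subject_id"]).set_index("subject_id")
        cols = ["procedure", "time_h"] + [m for m in self.mediators if m in w.columns]
        return w[cols]

    def values_matrix(
        self,
        procedure: str | Sequence[str] | None = None,
        times: Iterable[int] | None = None,
    ) -> pd.DataFrame:
        """Like :meth:`wide` but mediator columns only."""
        w = self.wide(procedure, times)
        return w.drop(columns=["procedure", "time_h"])

    def cell_values(self, procedure: str, time_h: int, mediator: str) -> np.ndarray:
        """Concentrations for one mediator in one design cell."""
        d = self.data
        sel = (
            (d["procedure"] == procedure)
            & (d["time_h"] == time_h)
            & (d["mediator"] == mediator)
        )
        return d.loc[sel, "value"].to_numpy(dtype=float)

    def treated(self) -> "MediatorPanel":
        """Sub-panel with the UNTREATED baseline group removed."""
        return MediatorPanel(
            self.data[self.data["procedure"] != "UNTREATED"].copy(), self.mediators
        )

    # -- I/O -------------------------------------------------------------

    def write_csv(self, path: str | Path) -> None:
        out = self.data[list(REQUIRED_COLUMNS)].sort_values(
            ["procedure", "time_h", "subject_id", "mediator"]
        )
        out.to_csv(path, index=False)


def load_panel(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    strict_names: bool = True,
) -> MediatorPanel:
    """Read a long-format CSV into a validated :class:`MediatorPanel`.

    Mediator names are passed through the alias table (defaults to
    :data:`DEFAULT_ALIASES`); with ``strict_names`` any name that is neither
    canonical nor aliased raises :class:`PanelFormatError` rather than
    silently creating a new analyte column.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "procedure": str, "mediator": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"{path}: missing required columns {missing}")
    alias = dict(DEFAULT_ALIASES)
    if aliases:
        alias.update(aliases)
    df["mediator"] = df["mediator"].map(lambda m: alias.get(m, m))
    if strict_names:
        unknown = sorted(set(df["mediator"]) - set(MEDIATORS))
        if unknown:
            raise PanelFormatError(
                f"{path}: unknown mediator names {unknown}; supply an alias map"
            )
    df["time_h"] = df["time_h"].astype(int)
    df["value"] = df["value"].astype(float)
    _check_hard_invariants(df)
    return MediatorPanel(df.reset_index(drop=True))


def _check_hard_invariants(df: pd.DataFrame) -> None:
    if (~np.isfinite(df["value"])).any():
        raise DomainError("non-finite concentration values present")
    if (df["value"] < 0).any():
        bad = df.loc[df["value"] < 0].iloc[0]
        raise DomainError(
            f"negative concentration for subject {bad['subject_id']}, "
            f"mediator {bad['mediator']}"
        )
    unknown_proc = sorted(set(df["procedure"]) - set(PROCEDURES))
    if unknown_proc:
        raise PanelFormatError(f"unknown procedure labels {unknown_proc}")
    dup = df.duplicated(subset=["subject_id", "mediator"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise PanelIntegrityError(
            f"duplicate value for subject {bad['subject_id']}, "
            f"mediator {bad['mediator']}"
        )
    cells = df[["subject_id", "procedure", "time_h"]].drop_duplicates()
    multi = cells["subject_id"].duplicated()
    if multi.any():
        sid = cells.loc[multi, "subject_id"].iloc[0]
        raise PanelIntegrityError(
            f"subject {sid} appears at more than one (procedure, time) — "
            "destructive sampling allows exactly one"
        )
    baseline_mismatch = cells[
        (cells["procedure"] == "UNTREATED") != (cells["time_h"] == 0)
    ]
    if not baseline_mismatch.empty:
        sid = baseline_mismatch["subject_id"].iloc[0]
        raise PanelIntegrityError(
            f"subject {sid}: UNTREATED must coincide with time 0 (and vice versa)"
        )


def validate_panel(panel: MediatorPanel) -> list[Violation]:
    """Report-only validation of design completeness and replication."""
    out: list[Violation] = []
    df = panel.data
    if df.empty:
        out.append(Violation("error", "empty", "panel contains no records"))
        return out
    extra = sorted(set(panel.mediators) - set(MEDIATORS))
    if extra:
        out.append(
            Violation("warning", "noncanonical-mediators", f"non-canonical analytes: {extra}")
        )
    if "UNTREATED" not in set(df["procedure"]):
        out.append(Violation("error", "no-baseline", "no baseline group (UNTREATED, time 0)"))
    design = panel.design()
    for _, row in design.iterrows():
        if row["n"] < 2:
            out.append(
                Violation(
                    "warning",
                    "insufficient-replication",
                    f"cell ({row['procedure']}, {row['time_h']} h) has n={row['n']} "
                    "< 2: insufficient replication for t-test",
                )
            )
    # per-subject completeness across the mediator vocabulary
    counts = df.groupby("subject_id")["mediator"].nunique()
    incomplete = counts[counts != len(panel.mediators)]
    if not incomplete.empty:
        out.append(
            Violation(
                "warning",
                "incomplete-profiles",
                f"{len(incomplete)} subject(s) missing some mediator values",
            )
        )
    return out


def log_transform(panel: MediatorPanel, offset: float = 1.0) -> MediatorPanel:
    """Return a panel with values mapped to log10(value + offset).

    ``offset`` must be positive when zeros are present; the transform is
    strictly increasing so within-mediator ordering is preserved.
    """
    if offset < 0:
        raise DomainError("offset must be nonnegative")
    vals = panel.data["value"].to_numpy(dtype=float)
    if offset == 0 and (vals <= 0).any():
        raise DomainError("zero/negative values require a positive offset")
    df = panel.data.copy()
    df["value"] = np.log10(vals + offset)
    return MediatorPanel(df, panel.mediators)


def max_normalize(panel: MediatorPanel, scope: str = "whole_panel") -> MediatorPanel:
    """Rescale each mediator to [0, 1] by its maximum observed value.

    ``scope`` is ``"whole_panel"`` (one max per mediator across all samples)
    or ``"per_procedure"`` (max taken within each procedure arm separately,
    baseline counted with neither treated arm).  An all-zero mediator stays
    all-zero.
    """
    if scope not in ("whole_panel", "per_procedure"):
        raise ValueError(f"unknown scope {scope!r}")
    df = panel.data.copy()
    keys = ["mediator"] if scope == "whole_panel" else ["procedure", "mediator"]
    gmax = df.groupby(keys, observed=True)["value"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(gmax.to_numpy() > 0, df["value"].to_numpy() / gmax.to_numpy(), 0.0)
    df["value"] = scaled
    return MediatorPanel(df, panel.mediators)
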