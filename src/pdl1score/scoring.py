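"""PD-L1 positivity calls and the three clinical scores.

A cell is PD-L1 positive when the DAB optical density in its class-specific
compartment reaches the threshold: tumor cells are judged on membranous
staining only (mean membrane DAB OD), immune cells on total-cell staining
(mean whole-cell DAB OD); stromal cells are never positive.  From the calls:

    TPS = 100 * (positive tumor cells) / (viable tumor cells)
    CPS = 100 * (positive tumor cells + positive immune cells)
              / (viable tumor cells),  capped at 100
    ICS = 100 * (area of positive immune cells) / (tumor area)

with clinical cutoff categories TPS {<1, >=1, >=50}, CPS {<1, >=1, >=20} and
ICS {<1, >=1, >=5}.  "Viable" tumor cells are all detected tumor-class cells
(the pipeline carries no necrosis class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CellClass

__all__ = ["DEFAULT_DAB_THRESHOLD_OD", "CUTOFFS", "call_positivity",
           "compute_scores", "ScoreReport", "score_category"]

# Central undocumented parameter of DAB-based positivity: the literature OD
# threshold. Exposed everywhere (config, CLI, report).
DEFAULT_DAB_THRESHOLD_OD = 0.2

CUTOFFS: dict[str, tuple[float, float]] = {
    "TPS": (1.0, 50.0),
    "CPS": (1.0, 20.0),
    "ICS": (1.0, 5.0),
}


def score_category(value: float | None, cutoffs: tuple[float, ...]) -> str | None:
    """Ordinal cutoff category of a score, ">=" convention.

    ``score_category(30, (1, 50)) == ">=1"``; None stays None.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if sorted(cutoffs) != list(cutoffs):
        raise ValueError("cutoffs must be strictly increasing")
    cat = f"<{cutoffs[0]:g}"
    for c in cutoffs:
        if value >= c:
            cat = f">={c:g}"
    return cat


def call_positivity(cells: pd.DataFrame, dab_threshold_od: float = DEFAULT_DAB_THRESHOLD_OD,
                    *, class_column: str = "cell_class",
                    membrane_od_column: str = "membrane_dab_mean",
                    cell_od_column: str = "cell_dab_mean") -> pd.DataFrame:
    """Flag each classified cell as PD-L1 positive or negative.

    ``cells`` must carry the cell class plus mean membrane and whole-cell DAB
    OD (as produced by the feature table).  Tumor cells are positive iff mean
    membrane DAB OD >= threshold, immune cells iff mean whole-cell DAB OD >=
    threshold (boundary inclusive), stromal cells are always negative.  Cells
    without a membrane compartment use the nucleus-boundary band OD recorded
    by the feature extractor (``membrane_fallback`` column, when present, is
    propagated for the report).
    """
    if not (dab_threshold_od > 0):
        raise ValueError("dab_threshold_od must be positive")
    out = cells.copy()
    cls = out[class_column].astype(str)
    decision = np.where(cls == CellClass.TUMOR.value,
                        out[membrane_od_column],
                        out[cell_od_column]).astype(float)
    positive = decision >= dab_threshold_od
    positive[cls.to_numpy() == CellClass.STROMAL.value] = False
    out["decision_od"] = decision
    out["positive"] = positive
    out["dab_threshold_od"] = dab_threshold_od
    return out


@dataclass
class ScoreReport:
    """Counts, areas and the resulting TPS/CPS/ICS with cutoff categories."""

    n_tumor: int
    n_tumor_pos: int
    n_immune: int
    n_immune_pos: int
    area_immune_pos_um2: float
    tumor_area_um2: float
    tps: float | None
    cps: float | None
    ics: float
    tps_defined: bool
    categories: dict = field(default_factory=dict)
    dab_threshold_od: float | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {
                "n_tumor": self.n_tumor, "n_tumor_pos": self.n_tumor_pos,
                "n_immune": self.n_immune, "n_immune_pos": self.n_immune_pos,
            },
            "areas_um2": {
                "area_immune_pos": self.area_immune_pos_um2,
                "tumor_area": self.tumor_area_um2,
            },
            "scores": {"TPS": self.tps, "CPS": self.cps, "ICS": self.ics},
            "categories": self.categories,
            "tps_defined": self.tps_defined,
            "dab_threshold_od": self.dab_threshold_od,
            "notes": self.notes,
        }

    def summary(self) -> str:
        fmt = lambda v: "undefined" if v is None else f"{v:.1f}"
        return (f"TPS {fmt(self.tps)} | CPS {fmt(self.cps)} | ICS {fmt(self.ics)} "
                f"({self.n_tumor_pos}/{self.n_tumor} tumor cells positive, "
                f"{self.n_immune_pos} positive immune cells, "
                f"tumor area {self.tumor_area_um2:.0f} um^2)")


def compute_scores(scored_cells: pd.DataFrame, tumor_area_um2: float,
                   *, dab_threshold_od: float | None = None,
                   class_column: str = "cell_class",
                   area_column: str = "cell_area_um2") -> ScoreReport:
    """TPS, CPS and ICS from positivity-scored cells and the tumor area.

    ``scored_cells`` needs the class column, a boolean ``positive`` column and
    the per-cell area column (ICS numerator = summed cell area of positive
    immune cells).  TPS and CPS are flagged undefined (None, not an error)
    when no tumor cell was detected.
    """
    if not (tumor_area_um2 > 0):
        raise ValueError("tumor_area_um2 must be positive")
    cls = scored_cells[class_column].astype(str)
    pos = scored_cells["positive"].astype(bool)
    is_tum = cls == CellClass.TUMOR.value
    is_imm = cls == CellClass.IMMUNE.value
    n_tumor = int(is_tum.sum())
    n_tumor_pos = int((is_tum & pos).sum())
    n_immune = int(is_imm.sum())
    n_immune_pos = int((is_imm & pos).sum())
    area_immune_pos = float(scored_cells.loc[is_imm & pos, area_column].sum())

    notes = []
    if n_tumor > 0:
        tps = 100.0 * n_tumor_pos / n_tumor
        cps = min(100.0, 100.0 * (n_tumor_pos + n_immune_pos) / n_tumor)
        defined = True
    else:
        tps = cps = None
        defined = False
        notes.append("no viable tumor cells: TPS and CPS undefined")
    ics = 100.0 * area_immune_pos / tumor_area_um2

    categories = {
        "TPS": score_category(tps, CUTOFFS["TPS"]),
        "CPS": score_category(cps, CUTOFFS["CPS"]),
        "ICS": score_category(ics, CUTOFFS["ICS"]),
    }
    return ScoreReport(n_tumor=n_tumor, n_tumor_pos=n_tumor_pos,
                       n_immune=n_immune, n_immune_pos=n_immune_pos,
                       area_immune_pos_um2=area_immune_pos,
                       tumor_area_um2=float(tumor_area_um2),
                       tps=tps, cps=cps, ics=ics, tps_defined=defined,
                       categories=categories,
                       dab_threshold_od=dab_threshold_od, notes=notes)
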