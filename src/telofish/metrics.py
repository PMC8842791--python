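"""Specimen- and cohort-level telomere metrics from the per-cell table.

Works on a tidy cell table with columns ``specimen_id``, ``tissue_class``,
``image_id``, ``cell_label``, ``compartment`` ("epithelial"/"stromal"),
``subtype`` ("mucus"/"non-mucus"/"unknown") and ``tfi``.

Metrics:

* epithelial/stromal ratio R — each epithelial cell's TFI divided by the mean
  TFI of all stromal cells *in the same image* (corrects per-image staining
  and exposure variation);
* specimen mean — arithmetic mean of a per-cell value pooled over all the
  specimen's cells (not a mean of image means);
* TLV (telomere length variation) — sample standard deviation (n-1) of the
  per-cell value within one specimen; a low TLV suggests clonal expansion;
* subtype means — per-specimen mean ratio of mucus vs non-mucus epithelial
  cells, suitable for a paired comparison across specimens.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "epithelial_stromal_ratios",
    "specimen_mean",
    "tlv",
    "subtype_means",
    "summarize_specimens",
]

SPECIMEN_COLUMNS = ["specimen_id", "tissue_class", "n_cells", "mean_tfi",
                    "mean_ratio", "mucus_mean_ratio", "nonmucus_mean_ratio", "tlv"]


def _select(cells: pd.DataFrame, value: str) -> pd.Series:
    if value not in ("tfi", "ratio"):
        raise ValueError("value must be 'tfi' or 'ratio'")
    if value not in cells.columns:
        raise ValueError(f"cell table has no {value!r} column")
    return cells[value].dropna()


def epithelial_stromal_ratios(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-epithelial-cell ratio R = tfi / mean(stromal tfi of the same image).

    Returns the epithelial rows with an added ``ratio`` column; stromal cells
    receive no ratio.  An image without stromal cells is an error — there is
    no silent fallback to cohort-level stroma.
    """
    if "image_id" not in cells.columns:
        cells = cells.assign(image_id=cells["specimen_id"])
    out = []
    for image_id, grp in cells.groupby("image_id", sort=False):
        stromal = grp.loc[grp["compartment"] == "stromal", "tfi"]
        epi = grp[grp["compartment"] == "epithelial"]
        if len(epi) == 0:
            continue
        if len(stromal) == 0:
            raise ValueError(f"image {image_id!r} has no stromal cells; "
                             "cannot compute epithelial/stromal ratio")
        ref = float(stromal.mean())
        if ref <= 0:
            raise ValueError(f"image {image_id!r}: mean stromal TFI is {ref:g}, "
                             "ratio undefined")
        out.append(epi.assign(ratio=epi["tfi"] / ref))
    if not out:
        return cells.iloc[0:0].assign(ratio=pd.Series(dtype=float))
    return pd.concat(out, ignore_index=True)


def specimen_mean(cells: pd.DataFrame, value: str = "tfi") -> tuple[float, int]:
    """Arithmetic mean of the chosen per-cell value over one specimen.

    Cells are pooled across the specimen's images (every cell weighs the
    same, regardless of image).  Returns ``(mean, n_contributing)``.
    """
    vals = _select(cells, value)
    if len(vals) == 0:
        raise ValueError("no contributing cells for specimen mean")
    return float(vals.mean()), int(len(vals))


def tlv(cells: pd.DataFrame, value: str = "tfi") -> float:
    """Telomere length variation: sample SD (n-1) of the per-cell value."""
    vals = _select(cells, value)
    if len(vals) < 2:
        raise ValueError("TLV needs at least 2 contributing cells")
    return float(vals.std(ddof=1))


def subtype_means(cells: pd.DataFrame, value: str = "ratio") -> tuple[float, float]:
    """Mean value of mucus and non-mucus epithelial cells of one specimen.

    Returns ``(mucus_mean, nonmucus_mean)``; a missing subtype yields NaN for
    its side, so paired comparisons across specimens can drop incomplete
    pairs.  Cells with subtype "unknown" are ignored here (they still count
    toward compartment-level metrics).
    """
    epi = cells[cells["compartment"] == "epithelial"]
    res = []
    for subtype in ("mucus", "non-mucus"):
        sel = _select(epi[epi["subtype"] == subtype], value) if len(epi) else pd.Series(dtype=float)
        res.append(float(sel.mean()) if len(sel) else float("nan"))
    return res[0], res[1]


def summarize_specimens(cells: pd.DataFrame, tlv_value: str = "tfi",
                        with_ratios: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-specimen summary table.

    Parameters
    ----------
    cells : tidy per-cell table (see module docstring)
    tlv_value : "tfi" or "ratio" — which per-cell value TLV is computed on.
        With "ratio", TLV uses epithelial cells only (stromal cells have no
        ratio); with "tfi" it uses every cell of the specimen.
    with_ratios : compute epithelial/stromal ratios (requires stromal cells
        in every image that has epithelial cells).

    Returns
    -------
    specimens : one row per specimen (see ``SPECIMEN_COLUMNS``)
    ratios : per-epithelial-cell ratio table (empty when ``with_ratios`` is
        off)
    """
    cells = cells.copy()
    if "image_id" not in cells.columns:
        cells["image_id"] = cells["specimen_id"]
    if with_ratios:
        ratios = epithelial_stromal_ratios(cells)
    else:
        ratios = cells.iloc[0:0].assign(ratio=pd.Series(dtype=float))

    rows = []
    for sid, grp in cells.groupby("specimen_id", sort=False):
        tissue = grp["tissue_class"].iloc[0]
        mean_tfi, n = specimen_mean(grp, "tfi")
        rgrp = ratios[ratios["specimen_id"] == sid] if len(ratios) else ratios
        mean_ratio = float(rgrp["ratio"].mean()) if len(rgrp) else float("nan")
        mucus, nonmucus = subtype_means(rgrp) if len(rgrp) else (float("nan"),) * 2
        tlv_src = rgrp.rename(columns={}) if tlv_value == "ratio" else grp
        try:
            spread = tlv(tlv_src, tlv_value)
        except ValueError:
            spread = float("nan")
            logger.warning("specimen %s: fewer than 2 cells for TLV", sid)
        rows.append(dict(specimen_id=sid, tissue_class=tissue, n_cells=n,
                         mean_tfi=mean_tfi, mean_ratio=mean_ratio,
                         mucus_mean_ratio=mucus, nonmucus_mean_ratio=nonmucus,
                         tlv=spread))
    specimens = pd.DataFrame(rows, columns=SPECIMEN_COLUMNS)
    return specimens, ratios
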