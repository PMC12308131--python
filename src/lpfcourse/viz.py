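"""Per-patient four-panel disease-course figure.

Panels share an x-axis of patient age (baseline age plus elapsed
years).  From the bottom up:

1. stacked lesion-volume bars (ml) per subcompartment, drawn only at
   time points with at least one actually measured (not filled) MRI;
   the y-axis is split, the lower half spanning 0-2 ml and the upper
   half 2-14 ml, so low and high lesion loads share one layout;
2. parenchymal percentile lines per compartment with dots at measured
   time points;
3. stacked compartment-weighted LPF percentiles, topped by the weighted
   sum ("cumulative LPF", default weights cerebral 1, infratentorial
   2.5, cervical 3.8), with grey shading where a compartment has no
   measurement yet;
4. EDSS line with a normalized FSS colour wheel per clinical visit and
   an ambulation arc; the background changes shade at SPMS conversion.

Compartment colour families: cord reds, infratentorial yellows,
cerebral greens; the visual functional system (no MRI correlate) is
grey.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Wedge  # noqa: E402

from .io import (
    CEREBRAL_SUBCOMPARTMENTS,
    COMPARTMENTS,
    CORD_SUBCOMPARTMENTS,
    FSS_COLUMNS,
    INFRATENTORIAL_SUBCOMPARTMENTS,
    CompartmentTriple,
)

#: subcompartment stacking order and colours per compartment family
_SUBCOLORS = {
    "cord": (CORD_SUBCOMPARTMENTS, ["#67000d", "#fb6a4a"]),
    "infra": (INFRATENTORIAL_SUBCOMPARTMENTS,
              ["#7f4f00", "#b8860b", "#daa520", "#ffd24d"]),
    "cereb": (CEREBRAL_SUBCOMPARTMENTS, ["#00441b", "#238b45", "#74c476"]),
}
_COMP_COLOR = {"cord": "#cb181d", "infra": "#daa520", "cereb": "#238b45"}
_FSS_FAMILY = {
    "fss_pyramidal": "#67000d", "fss_sensory": "#cb181d",
    "fss_bowel_bladder": "#fb6a4a",
    "fss_brainstem": "#b8860b", "fss_cerebellar": "#ffd24d",
    "fss_mental": "#238b45", "fss_visual": "#888888",
}
_FSS_MAX = {"fss_pyramidal": 6, "fss_cerebellar": 5, "fss_brainstem": 5,
            "fss_sensory": 6, "fss_bowel_bladder": 6, "fss_visual": 6,
            "fss_mental": 5}


@dataclass
class VizConfig:
    """Rendering configuration; defaults follow the published conventions:
    weights cerebral 1 / infratentorial 2.5 / cervical 3.8, lesion axis
    split at 2 ml with a 14 ml ceiling."""

    weights: CompartmentTriple = field(
        default_factory=lambda: CompartmentTriple(cord=3.8, infra=2.5, cereb=1.0))
    lesion_axis_split_ml: float = 2.0
    lesion_axis_max_ml: float = 14.0
    dpi: int = 110
    output_format: str = "png"

    def __post_init__(self):
        self.weights = CompartmentTriple.from_any(self.weights)
        w = self.weights.as_dict()
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be nonnegative")
        if not 0 < self.lesion_axis_split_ml < self.lesion_axis_max_ml:
            raise ValueError("lesion axis split must lie below the axis maximum")

    def config_hash(self) -> str:
        payload = json.dumps({"weights": self.weights.as_dict(),
                              "split": self.lesion_axis_split_ml,
                              "max": self.lesion_axis_max_ml}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def cumulative_weighted_lpf(lpf_pct: pd.DataFrame,
                            weights: CompartmentTriple
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Stacked compartment bands and the weighted top line.

    ``lpf_pct`` has columns ``lpf_cord_pct, lpf_infra_pct, lpf_cereb_pct``
    sharing one date index.  Band heights are ``w_k * LPFpct_k`` stacked
    cord, infratentorial, cerebral; the top line is their sum, so band
    heights conserve the total at every date.  Missing values propagate
    (rendered as grey no-data regions).
    """
    w = weights.as_dict()
    bands = pd.DataFrame(index=lpf_pct.index)
    for comp in COMPARTMENTS:
        bands[comp] = w[comp] * lpf_pct[f"lpf_{comp}_pct"]
    top = bands.sum(axis=1, skipna=False)
    return bands, top


def _fss_wheel(ax, x: float, y: float, scores: dict[str, float],
               ambulation: bool, radius_x: float, radius_y: float) -> None:
    """Normalized FSS colour wheel: one 1/7 sector per functional system,
    filled radially in proportion to score / max score; ambulation drawn
    as a partial black arc around the wheel."""
    n = len(FSS_COLUMNS)
    for k, col in enumerate(FSS_COLUMNS):
        theta1, theta2 = 90 - (k + 1) * 360 / n, 90 - k * 360 / n
        frac = 0.0
        if col in scores and not pd.isna(scores[col]):
            frac = float(scores[col]) / _FSS_MAX[col]
        ax.add_patch(Wedge((x, y), radius_x * max(frac, 0.04), theta1, theta2,
                           facecolor=_FSS_FAMILY[col] if frac > 0 else "#dddddd",
                           edgecolor="none", zorder=5,
                           transform=ax.transData))
        ax.add_patch(Wedge((x, y), radius_x, theta1, theta2, width=0.0,
                           facecolor="none", edgecolor="#cccccc",
                           linewidth=0.3, zorder=5))
    if ambulation:
        ax.add_patch(Wedge((x, y), radius_x * 1.25, -90, 90, width=radius_x * 0.18,
                           facecolor="black", edgecolor="none", zorder=6))


def _measured_mri_dates(patient_rows: pd.DataFrame) -> pd.Series:
    """True where a row has at least one lesion measure with provenance
    ``measured`` (a real, unfilled MRI)."""
    lesion_src = [c + "_src" for c in
                  CEREBRAL_SUBCOMPARTMENTS + INFRATENTORIAL_SUBCOMPARTMENTS
                  + CORD_SUBCOMPARTMENTS if c + "_src" in patient_rows.columns]
    if not lesion_src:
        return pd.Series(False, index=patient_rows.index)
    return (patient_rows[lesion_src] == "measured").any(axis=1)


def render_patient(matched: pd.DataFrame, features: pd.DataFrame,
                   patient_id: str, out_path: str | Path,
                   config: VizConfig | None = None,
                   onset_date: pd.Timestamp | None = None,
                   phenotype_label: str | None = None) -> Path:
    """Render one patient's four-panel figure to ``out_path``.

    ``matched`` is the provenance-carrying matched frame, ``features``
    the percentile feature table (rows of other patients are ignored).
    ``onset_date``, when given, shifts the background shade at SPMS
    conversion.
    """
    config = config or VizConfig()
    rows = matched[matched["patient_id"] == patient_id].sort_values("date")
    if not len(rows):
        raise ValueError(f"no matched time points for patient {patient_id!r}")
    feat = features[features["patient_id"] == patient_id].sort_values("date")

    age0 = float(feat["age0"].iloc[0]) if len(feat) else float(
        rows["age"].dropna().iloc[0])
    t0 = rows["date"].min()
    ages = age0 + (pd.to_datetime(rows["date"]) - t0).dt.days / 365.25
    rows = rows.assign(_age=ages.to_numpy())
    feat_ages = age0 + (pd.to_datetime(feat["date"]) - t0).dt.days / 365.25

    fig, axes = plt.subplots(
        4, 1, sharex=True, figsize=(10, 9),
        gridspec_kw={"height_ratios": [2.2, 1.4, 1.8, 1.6]})
    ax_edss, ax_lpf, ax_par, ax_les = axes

    if onset_date is not None:
        onset_age = age0 + (pd.Timestamp(onset_date) - t0).days / 365.25
        for ax in axes:
            ax.axvspan(rows["_age"].min() - 0.5, onset_age,
                       color="#eaf2fb", zorder=0)
            ax.axvspan(onset_age, rows["_age"].max() + 0.5,
                       color="#c9ddf2", zorder=0)

    # --- bottom: stacked lesion bars at measured MRI dates, split axis ----
    measured = _measured_mri_dates(rows)
    bar_rows = rows[measured.to_numpy()]
    split, top_ml = config.lesion_axis_split_ml, config.lesion_axis_max_ml

    def squash(v):  # lower half of the axis covers 0..split, upper covers split..max
        v = np.asarray(v, dtype=float)
        return np.where(v <= split, v / split * 0.5,
                        0.5 + (v - split) / (top_ml - split) * 0.5)

    bottoms = np.zeros(len(bar_rows))
    for comp in COMPARTMENTS:
        subs, colors = _SUBCOLORS[comp]
        for sub, color in zip(subs, colors):
            heights = bar_rows[sub].fillna(0.0).to_numpy(dtype=float)
            tops = bottoms + heights
            ax_les.bar(bar_rows["_age"], squash(tops) - squash(bottoms),
                       bottom=squash(bottoms), width=0.22, color=color,
                       label=sub.replace("_ml", "").replace("_", " "))
            bottoms = tops
    ax_les.axhline(0.5, color="#999999", linewidth=0.6, linestyle=":")
    ticks_ml = [0, 1, 2, 6, 10, 14]
    ax_les.set_yticks(squash(np.array(ticks_ml, dtype=float)))
    ax_les.set_yticklabels([str(v) for v in ticks_ml])
    ax_les.set_ylim(0, 1.02)
    ax_les.set_ylabel("lesion volume (ml)")
    ax_les.set_xlabel("age (years)")

    # --- parenchymal percentiles ------------------------------------------
    for comp in COMPARTMENTS:
        col = f"p_{comp}_pct"
        if col in feat.columns:
            ax_par.plot(feat_ages, feat[col], color=_COMP_COLOR[comp],
                        linewidth=1.4)
            src_col = {"cord": "mucca_mm2_src", "infra": "p_infra_src",
                       "cereb": "p_cereb_src"}[comp]
            if src_col in rows.columns:
                meas_dates = rows.loc[rows[src_col] == "measured", "date"]
                pts = feat[feat["date"].isin(meas_dates)]
                pts_age = age0 + (pd.to_datetime(pts["date"]) - t0).dt.days / 365.25
                ax_par.plot(pts_age, pts[col], "o", color=_COMP_COLOR[comp],
                            markersize=4)
    ax_par.set_ylim(0, 100)
    ax_par.set_ylabel("parenchymal\nvolume (pctl)")

    # --- stacked weighted LPF ---------------------------------------------
    lpf_cols = [f"lpf_{c}_pct" for c in COMPARTMENTS]
    lpf_all = rows.merge(feat[["date"] + lpf_cols], on="date", how="left")
    bands, top = cumulative_weighted_lpf(
        lpf_all.set_index("_age")[lpf_cols], config.weights)
    nodata = top.isna().to_numpy()
    base = np.zeros(len(bands))
    for comp in COMPARTMENTS:
        h = bands[comp].to_numpy(dtype=float)
        ax_lpf.fill_between(bands.index, base, base + np.nan_to_num(h),
                            where=~nodata, color=_COMP_COLOR[comp],
                            alpha=0.75, linewidth=0)
        base = base + np.nan_to_num(h)
    if nodata.any():
        ymax = np.nanmax(top.to_numpy()) if not np.all(nodata) else 1.0
        ax_lpf.fill_between(bands.index, 0, max(ymax, 1.0), where=nodata,
                            color="#bbbbbb", alpha=0.5, linewidth=0,
                            label="no data")
    ax_lpf.plot(top.index, top, color="#1f4e9c", linewidth=1.8)
    ax_lpf.set_ylabel("LPF\n(cumulative pctl)")

    # --- EDSS + FSS wheels -------------------------------------------------
    edss_rows = rows.dropna(subset=["edss"])
    ax_edss.plot(edss_rows["_age"], edss_rows["edss"], color="#1f4e9c",
                 linewidth=1.8, zorder=3)
    ax_edss.set_ylim(-0.6, 10.5)
    ax_edss.set_ylabel("EDSS")
    clinical_rows = rows[rows["edss_src"] == "measured"] \
        if "edss_src" in rows.columns else edss_rows
    span_x = max(rows["_age"].max() - rows["_age"].min(), 1.0)
    r_x = 0.016 * span_x * 10
    for _, row in clinical_rows.iterrows():
        if pd.isna(row["edss"]):
            continue
        scores = {c: row.get(c, np.nan) for c in FSS_COLUMNS}
        _fss_wheel(ax_edss, float(row["_age"]), float(row["edss"]), scores,
                   bool(row.get("ambulation_affected", 0.0) or False),
                   radius_x=min(r_x, 0.35), radius_y=0.4)
    if phenotype_label:
        ax_edss.set_title(f"{patient_id} — {phenotype_label}", loc="left",
                          fontsize=11)
    else:
        ax_edss.set_title(str(patient_id), loc="left", fontsize=11)

    fig.align_ylabels(axes)
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=config.dpi,
                metadata=_metadata(config, out_path.suffix))
    plt.close(fig)
    return out_path


def _metadata(config: VizConfig, suffix: str) -> dict | None:
    if suffix.lower() == ".png":
        return {"Software": f"lpfcourse (config {config.config_hash()})"}
    return None


def render_cohort(matched: pd.DataFrame, features: pd.DataFrame,
                  phenotypes: pd.DataFrame | None, out_dir: str | Path,
                  config: VizConfig | None = None) -> pd.DataFrame:
    """Render every patient to ``<patient_id>.<fmt>`` plus an index listing.

    Partial failures are collected in the returned index (column
    ``error``), not raised.  Returns the index frame, also written as
    ``index.csv``.
    """
    config = config or VizConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pheno = {}
    if phenotypes is not None and len(phenotypes):
        pheno = phenotypes.set_index("patient_id").to_dict("index")
    records = []
    for pid in sorted(matched["patient_id"].unique()):
        entry = pheno.get(pid, {})
        label = "progressing" if entry.get("progressing") else "non-progressing"
        onset = entry.get("onset_date")
        path = out_dir / f"{pid}.{config.output_format}"
        rec = {"patient_id": pid, "phenotype": label if entry else "",
               "file": path.name, "error": ""}
        try:
            render_patient(matched, features, pid, path, config,
                           onset_date=onset if pd.notna(onset) else None,
                           phenotype_label=label if entry else None)
        except Exception as exc:  # noqa: BLE001 - collected, not fatal
            rec["error"] = str(exc)
        records.append(rec)
    index = pd.DataFrame(records,
                         columns=["patient_id", "phenotype", "file", "error"])
    index.to_csv(out_dir / "index.csv", index=False, lineterminator="\n")
    return index
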