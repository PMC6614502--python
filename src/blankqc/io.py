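"""Peak-table and injection-sequence I/O.

A *peak table* bundles four feature x injection matrices (peak area,
retention time, peak width, detection status) with per-feature metadata
(m/z, median RT) and the ordered injection sequence.  The sequence carries
the batch structure this package analyses: a leading block of conditioning
QCs followed by repeated deconditioning/conditioning cycles, each opened by
a group of extraction blanks and followed by replicate sample injections.

Tables are plain delimited text (tab by default, comma accepted) so they
can be produced from any peak picker's export.  Two dialects are read:

* wide -- one row per feature; columns ``feature_id, mz, rt_median`` then
  ``area_<run>``, ``rt_<run>``, ``width_<run>`` for every run order;
* long -- columns ``feature_id, run_order, area, rt, width``.

The optional detection matrix records pre-gap-filling detection status;
when absent, detection falls back to thresholding the (gap-filled) areas.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "PeakTableError",
    "annotate_sequence",
    "read_peak_table",
    "write_peak_table",
    "write_results",
]

SAMPLE_CLASSES = ("QC", "sample", "blank")

#: cycles opened by this many blanks are "intense"; a single blank is "mild"
INTENSE_BLANKS = 3


class PeakTableError(ValueError):
    """Raised when a peak table or sequence fails validation."""


@dataclass
class PeakTable:
    """Feature x injection peak table with sequence annotation.

    Attributes
    ----------
    features : DataFrame indexed by feature_id with columns ``mz`` (Da) and
        ``rt_median`` (min).
    sequence : DataFrame indexed by run_order (1-based, gap-free) with
        columns ``sample_class``, ``cycle_id``, ``blank_group_size``,
        ``position_after_blank`` and ``cycle_type``.
    area, rt, width : DataFrames (features x injections); area in arbitrary
        intensity units, rt and width in minutes.
    detected : boolean DataFrame of the same shape.
    """

    features: pd.DataFrame
    sequence: pd.DataFrame
    area: pd.DataFrame
    rt: pd.DataFrame
    width: pd.DataFrame
    detected: pd.DataFrame
    meta: dict = field(default_factory=dict)

    # -- basic API ---------------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.features.index

    @property
    def run_orders(self) -> pd.Index:
        return self.sequence.index

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.sequence)

    def injections_where(self, **conditions) -> pd.Index:
        """Run orders matching all equality conditions on sequence columns."""
        mask = pd.Series(True, index=self.sequence.index)
        for col, val in conditions.items():
            mask &= self.sequence[col] == val
        return self.sequence.index[mask]

    def subset_features(self, feature_ids) -> "PeakTable":
        idx = pd.Index(feature_ids)
        return PeakTable(
            features=self.features.loc[idx],
            sequence=self.sequence,
            area=self.area.loc[idx],
            rt=self.rt.loc[idx],
            width=self.width.loc[idx],
            detected=self.detected.loc[idx],
            meta=dict(self.meta),
        )

    def copy(self) -> "PeakTable":
        return PeakTable(
            features=self.features.copy(),
            sequence=self.sequence.copy(),
            area=self.area.copy(),
            rt=self.rt.copy(),
            width=self.width.copy(),
            detected=self.detected.copy(),
            meta=dict(self.meta),
        )

    def validate(self) -> "PeakTable":
        feats = self.features
        if feats.index.duplicated().any():
            dupes = feats.index[feats.index.duplicated()].unique().tolist()
            raise PeakTableError(f"duplicate feature_id: {dupes}")
        if (feats["mz"] <= 0).any():
            bad = feats.index[feats["mz"] <= 0][0]
            raise PeakTableError(f"non-positive m/z for feature {bad!r}")
        if (feats["rt_median"] < 0).any():
            bad = feats.index[feats["rt_median"] < 0][0]
            raise PeakTableError(f"negative rt_median for feature {bad!r}")

        shape = self.area.shape
        for name in ("rt", "width", "detected"):
            m = getattr(self, name)
            if m.shape != shape:
                raise PeakTableError(
                    f"matrix {name!r} shape {m.shape} != area shape {shape}"
                )
        if shape != (len(feats), len(self.sequence)):
            raise PeakTableError(
                f"matrix shape {shape} inconsistent with {len(feats)} features"
                f" x {len(self.sequence)} injections"
            )
        for name in ("area", "rt", "width"):
            vals = getattr(self, name).to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                i, j = np.argwhere(~np.isfinite(vals))[0]
                raise PeakTableError(
                    f"non-numeric {name} at feature {feats.index[i]!r}, "
                    f"run_order {self.sequence.index[j]}"
                )
        neg = self.area.to_numpy(dtype=float) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise PeakTableError(
                f"negative area at feature {feats.index[i]!r}, "
                f"run_order {self.sequence.index[j]}"
            )
        det = self.detected.to_numpy(dtype=bool)
        negw = (self.width.to_numpy(dtype=float) < 0) & det
        if negw.any():
            i, j = np.argwhere(negw)[0]
            raise PeakTableError(
                f"negative width at detected feature {feats.index[i]!r}, "
                f"run_order {self.sequence.index[j]}"
            )

        bad_cls = ~self.sequence["sample_class"].isin(SAMPLE_CLASSES)
        if bad_cls.any():
            ro = self.sequence.index[bad_cls][0]
            raise PeakTableError(
                f"unknown sample_class {self.sequence.loc[ro, 'sample_class']!r}"
                f" at run_order {ro}"
            )
        ro = self.sequence.index.to_numpy()
        if not np.array_equal(ro, np.arange(1, len(ro) + 1)):
            raise PeakTableError("run_order must be 1-based, increasing, gap-free")
        return self


def annotate_sequence(records: pd.DataFrame) -> pd.DataFrame:
    """Infer cycle structure from an ordered (run_order, sample_class) list.

    A maximal run of consecutive blanks opens a new cycle; the k-th sample
    after it (before the next blank run) gets ``position_after_blank = k``.
    Everything before the first blank -- the leading QC block plus any
    samples preceding the first blank -- belongs to cycle 0 and has no
    post-blank position.  Cycles opened by three blanks are labelled
    ``intense``, by a single blank ``mild``.

    Idempotent: depends only on the ordered class list; derived columns in
    the input are recomputed.
    """
    seq = records.copy()
    if "run_order" in seq.columns:
        seq = seq.set_index("run_order")
    seq.index = seq.index.astype(int)
    seq.index.name = "run_order"
    ro = seq.index.to_numpy()
    if not np.array_equal(ro, np.arange(1, len(ro) + 1)):
        raise PeakTableError("run_order must be 1-based, increasing, gap-free")
    classes = seq["sample_class"].to_numpy()
    bad = ~np.isin(classes, SAMPLE_CLASSES)
    if bad.any():
        raise PeakTableError(
            f"unknown sample_class {classes[bad][0]!r} at run_order {ro[bad][0]}"
        )

    n = len(classes)
    cycle_id = np.zeros(n, dtype=int)
    position = np.full(n, np.nan)
    group_size = np.zeros(n, dtype=int)

    cid = 0
    i = 0
    # cycle 0: everything before the first blank
    while i < n and classes[i] != "blank":
        i += 1
    while i < n:
        cid += 1
        start = i
        while i < n and classes[i] == "blank":
            i += 1
        g = i - start
        if g > INTENSE_BLANKS:
            warnings.warn(
                f"{g} consecutive blanks at run_order {ro[start]} exceeds "
                f"{INTENSE_BLANKS}; annotating anyway",
                stacklevel=2,
            )
        for b in range(start, start + g):
            cycle_id[b] = cid
            position[b] = b - start + 1
            group_size[b] = g
        k = 0
        while i < n and classes[i] != "blank":
            k += 1
            cycle_id[i] = cid
            if classes[i] == "sample":
                position[i] = k
            group_size[i] = g
            i += 1
        if k > 8:
            warnings.warn(
                f"{k} samples after the blank group at run_order {ro[start]}; "
                "designs use at most 8 conditioning samples",
                stacklevel=2,
            )

    seq["cycle_id"] = cycle_id
    seq["blank_group_size"] = group_size
    seq["position_after_blank"] = position
    type_map = {1: "mild", INTENSE_BLANKS: "intense"}
    seq["cycle_type"] = [
        type_map.get(g, "other") if c > 0 else "leading"
        for g, c in zip(group_size, cycle_id)
    ]
    return seq


# -- reading ---------------------------------------------------------------

def _read_delim(path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "\t"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                if "\t" not in line and "," in line:
                    sep = ","
                break
    return pd.read_csv(path, sep=sep, comment="#",
                       float_precision="round_trip", **kw)


def read_sequence(sequence_path) -> pd.DataFrame:
    seq = _read_delim(sequence_path)
    for col in ("run_order", "sample_class"):
        if col not in seq.columns:
            raise PeakTableError(f"sequence file missing column {col!r}")
    return annotate_sequence(seq[["run_order", "sample_class"]])


def read_peak_table(
    table_path,
    sequence_path,
    detection_path=None,
    detection_threshold: float = 0.0,
) -> PeakTable:
    """Read a peak table, its injection sequence and optional detection mask.

    When no detection matrix is given, ``detected := area > detection_threshold``
    (default 0), i.e. gap-filled zero/low areas count as not detected.
    """
    seq = read_sequence(sequence_path)
    raw = _read_delim(table_path)
    if "run_order" in raw.columns:  # long dialect
        need = {"feature_id", "run_order", "area", "rt", "width"}
        missing = need - set(raw.columns)
        if missing:
            raise PeakTableError(f"long peak table missing columns {sorted(missing)}")
        feats = (
            raw.groupby("feature_id", sort=False)
            .agg(mz=("mz", "first"), rt_median=("rt_median", "first"))
            if {"mz", "rt_median"} <= set(raw.columns)
            else pd.DataFrame(
                {"mz": np.nan, "rt_median": np.nan},
                index=raw["feature_id"].unique(),
            )
        )
        feats.index.name = "feature_id"
        mats = {}
        for name in ("area", "rt", "width"):
            mats[name] = raw.pivot(
                index="feature_id", columns="run_order", values=name
            ).loc[feats.index]
    else:  # wide dialect
        for col in ("feature_id", "mz", "rt_median"):
            if col not in raw.columns:
                raise PeakTableError(f"wide peak table missing column {col!r}")
        raw = raw.set_index("feature_id")
        feats = raw[["mz", "rt_median"]].copy()
        mats = {}
        for name in ("area", "rt", "width"):
            cols = [c for c in raw.columns
                    if c.startswith(name + "_") and c.split("_")[-1].isdigit()]
            if not cols:
                raise PeakTableError(f"no {name}_<run_order> columns found")
            sub = raw[cols].copy()
            sub.columns = [int(c.split("_")[-1]) for c in cols]
            mats[name] = sub.sort_index(axis=1)
    for name, m in mats.items():
        try:
            mats[name] = m.astype(float)
        except ValueError as exc:
            raise PeakTableError(f"non-numeric cell in {name} matrix: {exc}") from exc
        mats[name].columns = mats[name].columns.astype(int)
        mats[name].columns.name = "run_order"

    if detection_path is not None:
        det = _read_delim(detection_path)
        det = det.set_index("feature_id") if "feature_id" in det.columns else det
        det = det.astype(float).astype(bool)
        det.columns = mats["area"].columns
        det.index = mats["area"].index
    else:
        det = mats["area"] > detection_threshold

    table = PeakTable(
        features=feats,
        sequence=seq,
        area=mats["area"],
        rt=mats["rt"],
        width=mats["width"],
        detected=det,
    )
    return table.validate()


# -- writing ---------------------------------------------------------------

def _metadata_header(meta: dict | None) -> str:
    from blankqc import __version__

    meta = dict(meta or {})
    meta.setdefault("version", __version__)
    if "config_hash" not in meta:
        payload = repr(sorted((k, str(v)) for k, v in meta.items()))
        meta["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:12]
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict | None, index=True):
    buf = _io.StringIO()
    # %.17g guarantees bit-exact float round-trips through text
    df.to_csv(buf, sep="\t", index=index, float_format="%.17g")
    path.write_text(_metadata_header(meta) + buf.getvalue())


def write_peak_table(table: PeakTable, out_dir, meta: dict | None = None) -> dict:
    """Write a peak table as wide-format TSVs; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wide = table.features.copy()
    for name in ("area", "rt", "width"):
        m = getattr(table, name)
        m = m.rename(columns=lambda c: f"{name}_{c}")
        wide = wide.join(m)
    paths = {}
    paths["peak_table"] = out / "peak_table.tsv"
    _write_tsv(wide, paths["peak_table"], meta)
    paths["sequence"] = out / "sequence.tsv"
    _write_tsv(table.sequence[["sample_class"]], paths["sequence"], meta)
    paths["detection"] = out / "detection.tsv"
    _write_tsv(table.detected.astype(int), paths["detection"], meta)
    return paths


def write_results(tables: dict, out_dir, meta: dict | None = None) -> dict:
    """Write result tables as TSVs with a run-metadata header.

    ``tables`` maps a short name to a DataFrame; each is written to
    ``<out_dir>/<name>.tsv`` with commented header lines recording the
    package version, a config hash and the seed (when given), so reruns
    with identical configuration produce byte-identical data rows.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PeakTableError(f"cannot create output directory {out}: {exc}") from exc
    paths = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        _write_tsv(df, path, meta, index=df.index.name is not None)
        paths[name] = path
    return paths
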