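"""Experimental-metadata provenance: from record CSVs to per-(video, well) rows.

Experiments are described by a small set of CSV records compiled during
the tracking day: ``wormsorter.csv`` (strain/media/bacteria dispensed into
well ranges of each imaging plate), ``manual_metadata.csv`` (which plate
was imaged in which run on which instrument), ``sourceplate.csv``
(compound contents of source plates) and either ``robotlog.csv`` (the
liquid-handling robot's source-to-imaging well mapping, e.g. after column
shuffling) or ``imaging2source.csv`` (identity mapping).  These merge into
a plate metadata table (one row per (imaging plate, well)) and then, via
the recording index, into the final metadata table with one row per
(video filename, well of that camera's block).

Merges are pure functions of their inputs with fail-fast semantics:
unmatched keys raise instead of silently dropping rows.  Column schemas
are documented in ``docs/metadata_schemas.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import camera_block, expand_well_range

PLATE_METADATA_COLUMNS = [
    "imaging_plate_id", "well_name", "worm_strain", "media_type", "bacteria_strain",
    "compound_name", "compound_concentration", "concentration_units",
    "source_plate_id", "source_well",
]

FINAL_METADATA_COLUMNS = [
    "video_filename", "well_name", "imaging_plate_id", "run_number",
    "instrument_name", "camera_id", "date_yyyymmdd", "worm_strain", "media_type",
    "bacteria_strain", "compound_name", "compound_concentration",
    "concentration_units", "source_plate_id", "source_well",
]


def compile_plate_metadata(wormsorter: pd.DataFrame,
                           sourceplate: pd.DataFrame | None = None,
                           robotlog: pd.DataFrame | None = None,
                           imaging2source: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per (imaging_plate_id, well_name) with full well conditions.

    Well ranges in the wormsorter record are expanded to individual wells
    (overlaps are an error); compound contents, if any, are joined through
    the source-to-imaging well map — the robot log if shuffling was done,
    otherwise the identity mapping declared in ``imaging2source``.
    """
    rows = []
    seen: dict[tuple[str, str], str] = {}
    for _, rec in wormsorter.iterrows():
        plate = rec["imaging_plate_id"]
        for well in expand_well_range(str(rec["well_range"])):
            key = (plate, well)
            if key in seen:
                raise ValueError(
                    f"overlapping well ranges for plate {plate}: well {well} "
                    f"declared in {seen[key]!r} and {rec['well_range']!r}")
            seen[key] = str(rec["well_range"])
            rows.append({
                "imaging_plate_id": plate, "well_name": well,
                "worm_strain": rec["worm_strain"], "media_type": rec["media_type"],
                "bacteria_strain": rec["bacteria_strain"],
                "compound_name": np.nan, "compound_concentration": np.nan,
                "concentration_units": np.nan, "source_plate_id": np.nan,
                "source_well": np.nan,
            })
    plate_meta = pd.DataFrame(rows, columns=PLATE_METADATA_COLUMNS)
    plate_meta = plate_meta.astype({c: object for c in (
        "compound_name", "concentration_units", "source_plate_id", "source_well")})

    mapping = None
    if robotlog is not None:
        mapping = robotlog[["source_plate_id", "source_well",
                            "imaging_plate_id", "imaging_well"]].copy()
    elif imaging2source is not None:
        declared = set(zip(plate_meta["imaging_plate_id"], plate_meta["well_name"]))
        recs = []
        for _, rec in imaging2source.iterrows():
            for plate, well in declared:
                if plate == rec["imaging_plate_id"]:
                    recs.append({"source_plate_id": rec["source_plate_id"],
                                 "source_well": well,
                                 "imaging_plate_id": plate, "imaging_well": well})
        mapping = pd.DataFrame(recs)

    if mapping is not None and len(mapping):
        declared = set(zip(plate_meta["imaging_plate_id"], plate_meta["well_name"]))
        orphans = [f"{p}:{w}" for p, w in
                   zip(mapping["imaging_plate_id"], mapping["imaging_well"])
                   if (p, w) not in declared]
        if orphans:
            raise ValueError("imaging wells referenced by the well mapping but "
                             f"absent from wormsorter: {sorted(orphans)}")
        lookup = {(p, w): (sp, sw) for sp, sw, p, w in zip(
            mapping["source_plate_id"], mapping["source_well"],
            mapping["imaging_plate_id"], mapping["imaging_well"])}
        if sourceplate is not None:
            src = {(p, w): rec for (p, w), rec in
                   sourceplate.set_index(["source_plate_id", "well_name"]).iterrows()}
        else:
            src = {}
        for i in plate_meta.index:
            key = (plate_meta.at[i, "imaging_plate_id"], plate_meta.at[i, "well_name"])
            if key not in lookup:
                continue
            sp, sw = lookup[key]
            plate_meta.at[i, "source_plate_id"] = sp
            plate_meta.at[i, "source_well"] = sw
            rec = src.get((sp, sw))
            if rec is not None:
                plate_meta.at[i, "compound_name"] = rec["compound_name"]
                plate_meta.at[i, "compound_concentration"] = rec["compound_concentration"]
                plate_meta.at[i, "concentration_units"] = rec["concentration_units"]

    return (plate_meta.sort_values(["imaging_plate_id", "well_name"])
            .reset_index(drop=True))


def compile_final_metadata(plate_meta: pd.DataFrame, manual_metadata: pd.DataFrame,
                           videos: pd.DataFrame,
                           bad_wells: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per (video filename, well of that camera's block).

    ``videos`` is the recording index: video_filename, run_number,
    instrument_name, camera_id.  Videos join to the manual metadata on
    (run_number, instrument_name) — duplicates there or unmatched videos
    are errors.  ``bad_wells`` (imaging_plate_id, well_name) optionally
    adds an ``is_bad_well`` flag column.
    """
    key = ["run_number", "instrument_name"]
    if manual_metadata.duplicated(subset=key).any():
        dupes = manual_metadata.loc[manual_metadata.duplicated(subset=key), key]
        raise ValueError(f"duplicate (run, instrument) rows in manual metadata: "
                         f"{dupes.to_dict('records')}")
    manual_idx = manual_metadata.set_index(["run_number", "instrument_name"])
    plate_idx = plate_meta.set_index(["imaging_plate_id", "well_name"])

    rows = []
    for _, vid in videos.iterrows():
        mkey = (vid["run_number"], vid["instrument_name"])
        if mkey not in manual_idx.index:
            raise ValueError(f"video {vid['video_filename']!r} has no manual "
                             f"metadata row for run/instrument {mkey}")
        man = manual_idx.loc[mkey]
        plate = man["imaging_plate_id"]
        for well in camera_block(int(vid["camera_id"])):
            if (plate, well) not in plate_idx.index:
                raise ValueError(f"well {well} of plate {plate} missing from "
                                 "plate metadata")
            pm = plate_idx.loc[(plate, well)]
            rows.append({
                "video_filename": vid["video_filename"], "well_name": well,
                "imaging_plate_id": plate, "run_number": vid["run_number"],
                "instrument_name": vid["instrument_name"],
                "camera_id": vid["camera_id"],
                "date_yyyymmdd": man["date_yyyymmdd"],
                "worm_strain": pm["worm_strain"], "media_type": pm["media_type"],
                "bacteria_strain": pm["bacteria_strain"],
                "compound_name": pm["compound_name"],
                "compound_concentration": pm["compound_concentration"],
                "concentration_units": pm["concentration_units"],
                "source_plate_id": pm["source_plate_id"],
                "source_well": pm["source_well"],
            })
    final = pd.DataFrame(rows, columns=FINAL_METADATA_COLUMNS)
    final = final.sort_values(["video_filename", "well_name"]).reset_index(drop=True)
    if bad_wells is not None:
        flagged = set(zip(bad_wells["imaging_plate_id"], bad_wells["well_name"]))
        final["is_bad_well"] = [
            (p, w) in flagged
            for p, w in zip(final["imaging_plate_id"], final["well_name"])]
    return final


@dataclass
class ValidationReport:
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, detail: str):
        self.violations.append({"kind": kind, "detail": detail})

    def to_dict(self) -> dict:
        return {"ok": self.ok, "n_violations": len(self.violations),
                "violations": list(self.violations)}


def validate_metadata(final: pd.DataFrame) -> ValidationReport:
    """Uniqueness, completeness and orphan checks on a final metadata table."""
    report = ValidationReport()
    key = ["video_filename", "well_name"]
    dup = final.duplicated(subset=key)
    for _, row in final.loc[dup, key].iterrows():
        report.add("duplicate_row", f"{row['video_filename']}:{row['well_name']}")
    for vid, sub in final.groupby("video_filename"):
        cams = sub["camera_id"].unique()
        if len(cams) != 1:
            report.add("inconsistent_camera", vid)
            continue
        expected = set(camera_block(int(cams[0])))
        got = set(sub["well_name"])
        for w in sorted(expected - got):
            report.add("missing_well", f"{vid}:{w}")
        for w in sorted(got - expected):
            report.add("orphan_well", f"{vid}:{w}")
    for col in ("worm_strain", "imaging_plate_id", "run_number"):
        n_missing = int(final[col].isna().sum())
        if n_missing:
            report.add("missing_values", f"{col}: {n_missing} rows")
    return report
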