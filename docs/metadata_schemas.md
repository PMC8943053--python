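# Experiment-record CSV schemas (v1)

All files are UTF-8, comma-delimited, with a header row. Well names follow
the 96-well convention `A1`–`H12`. These schemas are defined by this
package; validators live in `plateworm.metadata`.

## wormsorter.csv

What the sorter dispensed into each block of wells of each imaging plate.

| column | type | notes |
|---|---|---|
| imaging_plate_id | str | unique per physical imaging plate |
| well_range | str | inclusive rectangle `A1-B12` (hyphen or en dash) or comma list `A1, B3` |
| worm_strain | str | |
| media_type | str | |
| bacteria_strain | str | |

Ranges of one plate must not overlap.

## manual_metadata.csv

One row per (run, plate): which plate was imaged on which instrument.

| column | type |
|---|---|
| date_yyyymmdd | int/str |
| run_number | int |
| imaging_plate_id | str |
| instrument_name | str |
| temperature_c | float |
| humidity_percent | float |

`(run_number, instrument_name)` must be unique.

## sourceplate.csv

Compound contents of source plates.

| column | type |
|---|---|
| source_plate_id | str |
| well_name | str |
| compound_name | str |
| compound_concentration | float |
| concentration_units | str |

## robotlog.csv

Source-to-imaging well mapping recorded by the liquid-handling robot
(e.g. after column shuffling).

| column | type |
|---|---|
| source_plate_id | str |
| source_well | str |
| imaging_plate_id | str |
| imaging_well | str |

Every `(imaging_plate_id, imaging_well)` must exist in the expanded
wormsorter record.

## imaging2source.csv

Identity mapping used when no shuffling was performed.

| column | type |
|---|---|
| imaging_plate_id | str |
| source_plate_id | str |

## video index (videos.csv)

One row per video file produced by the acquisition software.

| column | type | notes |
|---|---|---|
| video_filename | str | |
| run_number | int | joins to manual_metadata |
| instrument_name | str | joins to manual_metadata |
| camera_id | int | 1–6; selects the 4×4 well block |

## Final metadata (output)

One row per (video_filename, well of that camera's block), sorted by
(video_filename, well_name): all plate-metadata columns plus run_number,
instrument_name, camera_id and date_yyyymmdd; optionally `is_bad_well`
when a bad-well table is joined in.
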