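# Methods

This document records what `fulcrumtools` computes, the parameters it
exposes, and the numerical and design decisions behind them.

## Data model

A project lives under a fixed directory layout created by
`make_directory_structure`. Raw inputs are five CSV exports sharing a
filename prefix:

| file | role | key columns |
| --- | --- | --- |
| `<prefix>_field_sampling.csv` | one row per collection | `fulcrum_id`, `c_label`, date/time, GPS, temperatures, humidity |
| `<prefix>_field_sampling_sample_photo.csv` | photos per collection | `fulcrum_parent_id`, `exif_gps_latitude/longitude/dop` |
| `<prefix>_isolation.csv` | one row per isolation | `fulcrum_id`, `c_label`, `worms_on_sample` |
| `<prefix>_isolation_s_labeled_plates.csv` | plates per isolation | `fulcrum_parent_id`, `s_label` |
| `<prefix>_isolation_photos.csv` | photos per isolation | `fulcrum_parent_id` |

The isolation trio is optional but all-or-nothing: a project with one or two
of the three isolation files is malformed (`SchemaError`). In the isolation
table the `c_label` column holds the *collection record's* `fulcrum_id`, not
the printed label — the convention used by linked-app exports — and the join
resolves printed labels through the collection table.

All CSV reading uses UTF-8, RFC-4180 quoting, string dtype, and maps empty
cells to missing; no locale- or platform-dependent parsing is involved.
Processed tables are persisted as CSV plus a small JSON sidecar
(`<name>.csv.types.json`) recording boolean/integer/float columns, so round
trips restore dtypes without a binary format.

## Cleaning and flagging

**Fahrenheit detection.** A raw temperature strictly greater than the
threshold (default **40**) is assumed to be Fahrenheit and converted by
(v − 32) × 5⁄9; the row is flagged `flag_*_temperature_converted`. 40 °C is
above almost any plausible ambient or substrate reading at a field site but
below any plausible Fahrenheit entry for the same conditions, so the rule
separates the two scales cleanly; 40 itself is left unconverted (the
boundary is exclusive). The threshold is a `ProcessingConfig` parameter.

**Stuck probes.** Records are ordered by date, then time, then record id
(for a total, reproducible order), and a run of ≥ `run_length_min`
(default **3**) identical consecutive values in a temperature field is
flagged `flag_*_temperature_run`. Three repeats is short enough to catch a
probe that froze mid-transect and long enough that chance duplicates of a
0.1-degree reading rarely trigger it.

**Repairs are audited.** `fix_temperatures` can revert a conversion
(restoring the raw value exactly) or remove a value entirely; each action
appends an audit entry (record id, field, before, after, action). Reverting
a never-converted value is a recorded no-op, and unknown record ids raise.
Run flags are recomputed after any repair.

**Labels.** C-labels must match `^C-[0-9]+$` and S-labels `^S-[0-9]+$`
after trimming and upper-casing; deviations are flagged misformatted,
absences missing, and project-wide duplicates flagged on every occurrence.

**GPS.** Latitude/longitude outside [−90, 90] × [−180, 180] are nulled and
flagged. Configurable plausibility ranges (default −10…50 °C, −100…5500 m)
flag extreme-but-parseable values without altering them.

## Joining

The join produces one output row per S-labelled plate and one row for each
collection with no plates: the row count is exactly
Σ over collections of max(1, number of S-labels). Isolations whose parent
collection id resolves to nothing are retained and flagged as orphans rather
than dropped. Duplicate collection `fulcrum_id`s are a fatal
`IntegrityError` — they would silently multiply rows.

**Best photo.** Among a collection's photos the one with the smallest
`exif_gps_dop` (GPS dilution of precision, in meters; missing treated as
+∞) wins; ties break lexicographically by photo id so the choice is
deterministic. The final location prefers the best photo's EXIF GPS over the
record GPS (`location_source` ∈ {photo, record, none}) because the camera
fix is taken at the sample, while the record fix may be taken later.

**Outcome categories.** `worms_on_sample` is normalised to
present / absent / tracks_only / unknown.

## Geospatial annotation

Point-in-polygon is implemented directly as **even–odd ray casting** with an
explicit boundary test: points on an exterior edge or vertex count as
inside, points strictly inside a hole are outside, and points on a hole's
boundary count as inside. The primitive is deliberately hand-implemented and
exhaustively tested against an independent winding-number oracle (and
cross-checked against `shapely.covers` in the test suite only — shapely is
not a runtime dependency). GeoJSON `Polygon`/`MultiPolygon` features are
read with the standard library; each feature needs a `name` property and
rings are validated (≥ 3 distinct vertices, WGS-84 bounds). A collection
gets the first matching feature as `location` plus all matches in
`locations_all`; annotation is idempotent.

Even–odd and winding rules differ only for self-intersecting rings, which
the validator does not attempt to detect; test polygons are star-shaped so
the two rules provably coincide.

## Genotype integration

The genotyping sheet (CSV or TSV) requires `project_id`, `s_label`,
`species_id`, `possible_new_sp`, `strain_name`; the nematode schema adds
`proliferation`, `its2_genotype`, `ssu_genotype`. `check_genotypes` reports
malformed or duplicated S-labels, missing species or strain names, and the
two set differences (sheet-only vs. field-only S-labels). The merge is a
left join on the field table — no field row is ever lost; when the sheet
duplicates an S-label the first occurrence wins and the row is flagged.

## Photos

Each collection's best photo is copied byte-identically to
`<C-label>.jpg` and thumbnailed (aspect-preserving, default max dimension
300 px). Duplicate C-labels get `_2`, `_3`… suffixes. Missing or unreadable
files set `photo_status = "missing_raw"` and never abort the run.

## Report

The HTML report is a single self-contained file built with stdlib string
templating (the template is also written to `scripts/` for customisation).
The map uses Leaflet from a CDN; pin data are embedded as JSON in a
`<script type="application/json" id="pin-data">` block so tests and
downstream tools can parse them without rendering. Pin colours: present →
red, absent → blue, tracks only → orange, unknown → gray — one pin per
located collection.

Boxplots use **Tukey hinges**: with half = ⌊(n+1)/2⌋, each hinge is the
median of the lower/upper `half` order statistics (so the overall median is
included in both halves when n is odd); whiskers extend to the most extreme
data point within 1.5 × IQR of the hinges and anything beyond is an
outlier. This matches the classic five-number summary rather than any
interpolated quantile definition. SVG output is made deterministic by fixing
matplotlib's `svg.hashsalt` and stripping the date metadata; `deterministic
= True` additionally pins the report timestamp.

## Synthetic data generator

`generate_project(FixtureSpec(...), layout)` writes a complete fake
project — five CSVs, stub 16×12 JPEGs, a genotyping sheet, a two-sector
GeoJSON — plus `fixture_manifest.json` listing every injected anomaly and
the flag counts the pipeline is expected to raise. All randomness flows
from one `numpy.random.default_rng(seed)`; regeneration from the same spec
is byte-identical. Anomaly injection sets are mutually disjoint so the
expected counts are exact, and injected Fahrenheit values are drawn from
[60, 110] — unambiguously above the threshold after conversion too.

The generator emulates the *shape* of real exports (linked ids, label
grammar, plausible Hawaiian-island coordinates, DOP-ranked photos), not
their content: species are drawn from a fixed list, coordinates are uniform
in a bounding box, photos are solid-colour stubs without EXIF, and
collection dates sit in a narrow window. It is a test harness, not a
simulation of field ecology.

## Limitations

- Photo GPS travels in the photo CSV, not in EXIF tags; real EXIF parsing
  is out of scope.
- The Fahrenheit rule cannot distinguish a genuine 45 °C substrate reading
  (e.g. sun-baked rock) from a Fahrenheit entry; such values are converted
  and must be reverted via the audited repair path.
- Self-intersecting polygons are not detected; results for them follow the
  even–odd rule, which may differ from other conventions.
- The report's interactive map requires network access for the Leaflet CDN;
  all data in the report itself are embedded.
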