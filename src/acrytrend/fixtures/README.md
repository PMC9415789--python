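# Packaged fixtures

Hand-transcribed overview tables of European acrylamide biomonitoring
studies (2001–2017 literature in `table1_published.csv`, HBM4EU Aligned
Studies 2014–2021 in `table2_aligned.csv`), one CSV row per
study × sampling-year × smoking-stratum × analyte report. Empty cells mean
"not reported"; zero is always a real measurement.

## Transcription conventions

- Studies reporting both smoking strata in one printed cell are split into
  two rows using the printed participant counts (e.g. non-smokers 70,
  smokers 72).
- Combined strata value strings are split at the stratum boundary using the
  plausible magnitude of each biomarker (non-smoker adduct levels ~20–40
  pmol/g Hb, smokers ~50–160).
- `SC` (Chevolleau): the printed value strings cannot be unambiguously
  split across strata; they are kept as single non-smoker values in pmol/L.
  The study has no reported sampling year and is excluded from every
  analysis, so the convention has no downstream effect.
- `EH` (Hartmann) urinary AAMA range is printed "LOD–229" without a numeric
  LOD: the minimum is stored absent and `lod_unknown` is set. The blood
  AAVal range 15–71 accompanies the printed median 30.
- `UH` (Heudorf) reports the age band "5–6"; `mean_age` is stored as the
  midpoint 5.5. `KG2` (Goempel) prints only the 20–44 recruitment age
  window; `mean_age` is stored as the midpoint 32. Ages published as
  medians are stored as `mean_age` (best available central age).
- Multi-year sampling windows keep `year_start`/`year_end` as printed; the
  harmonizer assigns the midpoint year (e.g. 2007–2009 → 2008).
- Rows marked excluded in the source overview (overlapping datasets,
  missing sampling year, pre-2000 windows, 24 h-urine validation study)
  carry `excluded_flag` and a reason.
- Region grouping: north = {NO, SE, IS}, central_west = {DE, FR, LU, PL},
  south = {IT, PT, ES}.
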