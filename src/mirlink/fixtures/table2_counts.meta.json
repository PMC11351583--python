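{
  "name": "table2_counts",
  "description": "Per-sample mature miRNA read counts for 59 miRNAs across 4 case (A1R, A2R, A4R, A6R) and 3 control (B1R, B2R, B5R) right-ventricle myocardial samples, transcribed from the source publication's printed table with thousands separators stripped.",
  "caption_note": "The printed table is captioned as predicted miRNA-gene interactions, but its content is a per-sample count matrix: the column headers are sample identifiers and the trailing 'Gene Symbol' column holds mature miRNA names. This fixture treats the content as a count matrix and records the caption mismatch here.",
  "n_features": 59,
  "n_samples": 7,
  "case_samples": ["A1R", "A2R", "A4R", "A6R"],
  "control_samples": ["B1R", "B2R", "B5R"],
  "note_samples": "The study recruited four controls (B1R, B2R, B3R, B5R) but the printed table and PCA captions carry only three controls; the fixture carries the 7 printed samples as-is."
}
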