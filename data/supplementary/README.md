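# Published campaign tables (not distributed)

The three published-data acceptance tests validate the loader and the
round-wise analytics against the study's supplementary spreadsheets
("all medium combinations tested"), which are not redistributed with this
repository.  To run them:

1. Download the two supplementary data spreadsheets from the article's
   supplementary information.
2. Export each as CSV into this directory:
   - `supplementary_data_1.csv` — regular mode (302 media: 232 initial + 4 rounds)
   - `supplementary_data_2.csv` — time-saving mode (403 media)
3. Rename/relabel columns to match `data/dialects/supplementary.yaml`
   (or edit that dialect to match the export): one fold (or absolute
   concentration) column per component, `A450_<t>h_rep<i>`/`A450_<t>h_mean`
   readout columns, and `id`/`round`/`mode` metadata columns with rounds
   labelled `initial`, `round1` ... `round4`.

Without these files the three tests fail with a pointer to this README;
all other tests are fully synthetic and self-contained.
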