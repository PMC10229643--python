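# Dialect template for loading CSV exports of the published campaign tables
# (see data/supplementary/README.md).  Adjust the mappings to the actual
# column headers of the export:
#   id_column / round_column / mode_column : metadata column names
#   values   : "fold" if concentrations are stored as fold-of-EMEM,
#              "absolute" if stored in the component units (mM, %v/v)
#   component_columns : file column name -> component name, for any column
#              whose header differs from the built-in component names
# A450 columns are auto-detected as A450_<t>h_rep<i> / A450_<t>h_mean;
# rename the export's readout columns to that pattern.
id_column: id
round_column: round
mode_column: mode
values: fold
component_columns: {}
sep: ","
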