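# Editable per-group conversion parameters (placeholder defaults).
# nifh_copies_per_cell converts gene copies/L to cells/L; cell_rate_fmol_h
# is fmol N per cell per hour; active_hours the daily fixation window.
# Replace with literature averages for your application.
group,nifh_copies_per_cell,cell_rate_fmol_h,active_hours
Trichodesmium,2.0,1.5,12
UCYN-A,1.0,0.04,12
UCYN-B,1.0,0.2,12
Richelia,2.0,0.6,12
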