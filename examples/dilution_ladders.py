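"""Build the two oleic-acid dilution ladders and the sensitivity-group cuts.

The ladders are geometric in concentration (0.25 log10-unit steps). The
sensitivity boundaries divide each ladder's log span into three equal
parts; printed boundaries follow the two-significant-figure %w/v display
convention before conversion to mM.
"""

from fattaste import group_cuts, study1_series, study2_series

for name, series in (("study 1 (9 levels)", study1_series()), ("study 2 (12 levels)", study2_series())):
    print(f"\n=== {name} ===")
    print(series.to_frame().round(4).to_string(index=False))
    cuts = group_cuts(series)
    print(
        f"sensitivity cuts: {cuts.display_low_cut_mM:.2f} mM (high/medium) and "
        f"{cuts.display_high_cut_mM:.2f} mM (medium/low)"
    )
    print(
        "  -> assessors with detection thresholds below the lower cut are "
        "'high sensitivity'; above the upper cut, 'low sensitivity'."
    )
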