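"""How duplication structure biases the distinct-accession estimate.

Generates synthetic collection worlds with known founder counts and sweeps
one duplication knob at a time. IARC and within-country duplication inflate
the estimate (those copies are counted as distinct); missing origin data
deflate it (indigenous material stops being recognisable). The mean bias is
estimate minus true founder count, summed over the genus catalog
(320 founders per world), over 20 replicate worlds per grid point.
"""

from dataclasses import replace

from vaultgap.synthetic import SyntheticWorldConfig, bias_experiment

clean = SyntheticWorldConfig(
    p_cross_country_dup=0.0, p_iarc_dup=0.0,
    p_within_country_dup=0.0, p_missing_origin=0.0,
)

for knob in ("p_iarc_dup", "p_within_country_dup", "p_missing_origin"):
    grid = [replace(clean, **{knob: p}) for p in (0.0, 0.3, 0.6)]
    df = bias_experiment(grid, n_reps=20, seed=1)
    print(f"\nsweep of {knob}:")
    print(df[[knob, "mean_bias", "sd_bias"]].to_string(index=False))

print("\nPositive bias = overcount, negative = undercount; the clean world")
print("(all knobs zero) recovers the true founder counts exactly.")
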