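"""Parameter-recovery benchmark under increasing measurement noise.

Reproduces the simulation study at reduced scale: 4,000 transcripts with
log-uniform rates, multiplicative log-normal noise on all four intron/exon
abundances, full inversion, and Pearson correlations between estimated and
true log rates.
"""

from ssre import BenchmarkConfig, noise_curve

cfg = BenchmarkConfig(n_transcripts=4000, seed=11)
df = noise_curve(cfg, [0.0, 0.05, 0.10])

print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nfraction_estimated: share of transcripts whose observed ratios are\n"
    "compatible with the model (r_u < r_l < 1) and admit a rate estimate;\n"
    "corr_*: Pearson correlation of estimated vs true log rates. Noise-free\n"
    "recovery is near-perfect; at 10% noise roughly half the transcripts\n"
    "drop out and correlations settle around 0.7."
)
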