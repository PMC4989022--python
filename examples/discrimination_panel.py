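"""Analyse a 2-AFC fat-discrimination panel (guessing model + Thurstonian d').

Input: per-pair correct counts out of 51 assessors who chose the
"fattier" of two milk/cream samples under the taste-only condition
(mouthfeel and odour masked).  For each pair the module reports the
one-sided exact binomial p value, the proportion of true discriminators
pd = (pc - 1/2)/(1 - 1/2), the Thurstonian distance d' (pc = Phi(d'/sqrt 2))
and exact-binomial post-hoc power.
"""

from fattaste import PairDiscrimination, analyze_panel, sample_size

panel = [
    PairDiscrimination("0% vs 2.5%", 51, 33),
    PairDiscrimination("0% vs 5%", 51, 40),
    PairDiscrimination("0% vs 7.5%", 51, 39),
    PairDiscrimination("2.5% vs 5%", 51, 30),
    PairDiscrimination("7.5% vs 10%", 51, 29),
]

table = analyze_panel(panel, alpha=0.05)
cols = ["pair_label", "n_correct", "pct_discriminators", "p_value", "power", "d_prime"]
print(table[cols].round(3).to_string(index=False))
print(
    "\nPairs with p <= 0.05 are discriminable by taste alone; non-significant "
    "pairs with power < 80% (e.g. 2.5% vs 5%) cannot be claimed similar."
)

n = sample_size(alpha=0.05, target_power=0.80, pd_alt=0.30, guess_rate=0.5)
print(
    f"\nPlanning: detecting 30% discriminators with 80% power at alpha 0.05 "
    f"needs {n} assessors."
)
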