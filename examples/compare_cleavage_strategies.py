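"""Compare the side2 distributions for an 8-sided mother cell.

Prints the probability of each counterclockwise offset u (2..6) of the
second cleavage-plane endpoint under each strategy.  The rotation
strategies (rotNorm/rotTanNorm, stdbeta = 0.15) are more strongly
peaked at the even split (u = 4) than the Even-Binomial mixture with
probB = 0.3, which is what makes them better at reproducing empirical
polygon distributions.
"""

from epitopo import StrategyConfig, side2_pmf

OPTIONS = [
    ("evensplit", {}),
    ("random", {}),
    ("unevensplit", {}),
    ("Binomial", {}),
    ("Even-Binomial", {"probB": 0.3}),
    ("rotNorm", {"stdbeta": 0.15}),
    ("rotTanNorm", {"stdbeta": 0.15}),
]

i = 8
print(f"side2 offset distributions for an {i}-sided mother")
header = "option            " + "".join(f"   u={u}" for u in range(2, i - 1))
print(header)
for option, kw in OPTIONS:
    pmf = side2_pmf(i, StrategyConfig("RandN", option, "Random", **kw))
    row = "".join(f"  {p:.3f}" for p in pmf.probabilities)
    print(f"{option:<18s}{row}")
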