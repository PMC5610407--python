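"""Compare two classifiers on paired per-label decisions with McNemar tests.

Shows the two branches of the test — the chi-square approximation for 20 or
more discordant pairs and the exact binomial mid-P below that — plus the
Holm step-down correction applied when one label is compared against
several candidate models at once.
"""

from mule import PairedOutcome, holm_adjust, mcnemar

# a frequent label: model B corrects 45 of model A's errors, A corrects 18
frequent = PairedOutcome(n00=900, n01=18, n10=45, n11=37)
res = mcnemar(frequent)
print(f"frequent label: branch={res.branch}, statistic={res.statistic:.3f}, "
      f"p={res.p_value:.5f}")

# a rare label: only 9 discordant pairs, routed to the exact mid-P branch
rare = PairedOutcome(n00=980, n01=1, n10=8, n11=11)
res = mcnemar(rare)
print(f"rare label:     branch={res.branch}, p={res.p_value:.5f}")

# one label, three challengers: the family of p-values is Holm-adjusted,
# and a switch needs the *adjusted* p to clear the significance level
raw = [mcnemar(o).p_value for o in (
    PairedOutcome(940, 20, 55, 15),
    PairedOutcome(950, 30, 40, 10),
    PairedOutcome(960, 25, 28, 17),
)]
adjusted = holm_adjust(raw)
for i, (r, a) in enumerate(zip(raw, adjusted), start=2):
    verdict = "switchable" if a <= 0.1 else "not significant"
    print(f"candidate M{i}: raw p={r:.4f}  Holm-adjusted p={a:.4f}  -> {verdict}")
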