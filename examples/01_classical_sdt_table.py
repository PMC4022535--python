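"""Classical SDT on the published aggregate table.

Recomputes hit/false-alarm rates and d-prime for the nine group x valence
cells of the published three-group melancholia AGN table, from the
published counts, and prints them next to the published values.
"""

from hbsdt import REFERENCE_AGGREGATES, REFERENCE_RATES, sdt

print(f"{'cell':<32}{'rates (computed)':<20}{'d-prime':<10}published")
for key, counts in REFERENCE_AGGREGATES.items():
    group, valence = key
    rates = sdt.rates_from_counts(counts, round_2dp=True)
    dp = sdt.round_half_away(sdt.dprime(rates), 2)
    _, _, dp_printed = REFERENCE_RATES[key]
    print(f"{group + '/' + valence.value:<32}"
          f"{f'{rates.hit_rate:.2f}/{rates.fa_rate:.2f}':<20}"
          f"{dp:<10}{dp_printed}")

print(
    "\nd-prime = probit(hit rate) - probit(false-alarm rate); ~2 means the\n"
    "signal and noise strength distributions sit two SDs apart.  The\n"
    "melancholic group is least sensitive in every condition.  Small\n"
    "computed-vs-published differences trace to the published rates having\n"
    "been derived before pooling subjects (see docs/methods.md)."
)
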