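"""Hill numbers on toy abundance distributions.

Shannon entropy measures sampling uncertainty; converting it (and its
relatives) to an effective number of equally common species gives the "true
diversity" D_q, which behaves like a count: S equal species give D_q = S at
every order, and splitting every species in two doubles it.
"""

from sympair import AbundanceDistribution, hill_number, shannon_entropy

eight = AbundanceDistribution.from_counts([1] * 8)
sixteen = AbundanceDistribution.from_counts([1] * 16)
print(f"Shannon entropy (base 2), 8 equal species:  {shannon_entropy(eight, base=2):.3f} bits")
print(f"Shannon entropy (base 2), 16 equal species: {shannon_entropy(sixteen, base=2):.3f} bits")
print("-> entropy rises by one bit, but the second ecosystem is twice as diverse.")

for q in (0.0, 0.5, 1.0, 2.0):
    print(f"D_{q:<3} of 16 equal species: {hill_number(sixteen, q):.3f}")
print("-> every order reports the effective species count, 16.")

skewed = AbundanceDistribution((0.8, 0.2))
print(f"\nSkewed two-species community p = (0.8, 0.2):")
for q in (0.0, 0.5, 1.0, 2.0):
    print(f"D_{q:<3} = {hill_number(skewed, q):.4f}")
print("-> richness still counts 2; higher orders discount the rare species.")
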