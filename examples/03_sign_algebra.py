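"""Enumerate the direction-of-effect algebra of a quartet.

Each quartet has four signed source->target edges (sign of the marginal
regression slope per minor-allele copy).  Of the 2^4 = 16 possible
configurations, the 8 with an even number of up edges are consistent
(sign product +1); these quotient into 4 categories of 2 under two
binary symmetry criteria (genes axis / snps axis).
"""

from esnpquartets import all_sign_configurations, classify_category, classify_consistency


def fmt(config):
    return "(" + ", ".join("+" if e > 0 else "-" for e in config) + ")"


configs = all_sign_configurations()
consistent = [c for c in configs if classify_consistency(c)]
print(f"total configurations: {len(configs)}")
print(f"consistent (even number of up edges): {len(consistent)}")
print(f"inconsistent: {len(configs) - len(consistent)}")

categories = {}
for c in consistent:
    categories.setdefault(classify_category(c), []).append(c)
print(f"symmetry categories: {len(categories)}")
for (genes_axis, snps_axis), members in sorted(categories.items()):
    print(f"  genes {genes_axis:8s} / snps {snps_axis:8s}: "
          + ", ".join(fmt(m) for m in members))
# Edge order is (s1->g1, s1->g2, s2->g1, s2->g2); the two members of
# each category are global sign flips of one another.
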