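"""Discordant regions between a map order and reference-genome coordinates.

Constructs a 20-marker linkage group whose genome positions contain one
displaced inverted block and one misplaced singleton, and counts the
discordant regions with the longest-monotone-backbone rule.
"""

from radmap import count_discordant

order = [f"t{i:02d}" for i in range(20)]
positions = [10_000 * (i + 1) for i in range(20)]
positions[8:11] = [500_000, 490_000, 480_000]  # displaced, reversed block
positions[16] = 1_000  # misplaced singleton
genome = {m: ("Chr05", p) for m, p in zip(order, positions)}

report = count_discordant(order, genome)
print(f"majority chromosome : {report.chrom}")
print(f"discordant regions  : {report.n_dr} containing {report.n_markers_in_dr} markers")
print(f"region spans (map index ranges): {report.dr_spans}")
print(f"backbone retained   : {len(report.backbone)} of {len(report.aligned)} markers")
print("-> a span is a maximal run of consecutive markers that cannot sit on any")
print("   longest strictly monotone (either direction) backbone of genome positions;")
print("   a perfectly collinear group would report 0 regions.")
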