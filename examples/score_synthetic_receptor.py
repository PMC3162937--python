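"""Rank the TM residues of one receptor by subfamily-specific conservation.

Builds a synthetic 600-sequence alignment of 10 subfamilies (the focal one
carrying 5 planted binding columns, with enough within-subfamily background
similarity for the tree to find it), reconstructs the subfamily tree with
neighbor joining, and runs the two-entropy scorer end-to-end.
"""

from sstea import (
    SyntheticSpec,
    build_nj_tree,
    generate_msa,
    p_distance_matrix,
    parse_bw,
    score_receptor,
)

spec = SyntheticSpec(relatedness=0.5, seed=42)
aln, truth = generate_msa(spec)
tree = build_nj_tree(p_distance_matrix(aln))

receptor = "SF00_R000"
table = score_receptor(aln, tree, receptor, min_size=50, max_size=300)

print(f"receptor {receptor}: scored over branches of sizes {table.subfamily_sizes}")
print("top 10 positions (rank, BW position, score, planted role):")
for pos in table.ranking()[:10]:
    role = truth.position_role[pos]
    row = table.table[table.table["position"] == str(pos)].iloc[0]
    print(f"  {int(row['rank']):3d}  {str(pos):5s}  {row['score']:.3f}  {role}")

planted = truth.binding_positions(0)
ranks = sorted(table.rank_of(p) for p in planted)
print(f"\nplanted binding columns {sorted(map(str, planted))} hold ranks {ranks}")
print("(low score = conserved inside the subfamily, variable outside = binding-like)")
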