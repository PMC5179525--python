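"""Midpoint-root a gene tree and assign query genes to subfamilies.

Reference leaves (here r1..r3) carry known subfamily labels; query genes
inherit the label of the reference clade they fall into, with a supported
flag when the clade's bootstrap support exceeds 80.
"""

from lrrfam.phylo_classify import assign_subfamilies, load_tree, midpoint_root

tree = load_tree("(((q1:0.1,r1:0.12)91:0.2,r2:0.25)95:0.3,(r3:0.1,q2:0.4)88:0.2);")
rooted = midpoint_root(tree)
print(rooted.as_string(schema="newick").strip())

calls = assign_subfamilies(rooted, {"r1": "II", "r2": "II", "r3": "XII"})
for c in calls:
    star = "*" if c.monophyly_uncertain else ""
    print(f"{c.gene_id}: subfamily {c.subfamily}{star}  supported={c.supported}")
# q1 joins the subfamily II clade (support 91 > 80 -> supported), q2 joins
# XII; an asterisk would mark labels whose references are not monophyletic.
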