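"""Majority-rule consensus and the Brownian correlation matrix.

Takes a small sample of conflicting rooted trees, builds the 50%
majority-rule consensus (clades present in more than half of the trees,
branch lengths averaged over the supporting trees), resolves any
remaining polytomy with epsilon branches, and converts the result into
the species correlation matrix used as the phylogenetic random-effect
structure.
"""

import dendropy

from avimeta import TreeSample, majority_consensus, resolve_polytomies, tree_to_correlation


def tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


sample = TreeSample(
    trees=[
        tree("((A:1,B:1):1,(C:1,D:1):1);"),
        tree("((A:1,B:1):1,(C:1,D:1):1);"),
        tree("((A:1,C:1):1,(B:1,D:1):1);"),
    ]
)
consensus = majority_consensus(sample)  # AB and CD appear in 2/3 trees
print("consensus:", consensus.as_string(schema="newick").strip())

resolved = resolve_polytomies(consensus, epsilon=1e-8, seed=0)
corr = tree_to_correlation(resolved)
print("\nspecies correlation matrix (shared history / total depth):")
print(corr.to_frame().round(3).to_string())
# 0.5 means the pair shares half of its root-to-tip history under
# Brownian motion; 0 means they only meet at the root.
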