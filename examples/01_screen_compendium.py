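"""Expression screening: recover a planted co-expression module.

Builds a 30-dataset synthetic compendium in which the five query genes and
15 partner genes co-express through a shared latent factor in half of the
datasets, then screens every gene for co-expression evidence.
"""

from flowsig import PRIMARY_QUERIES, screen
from flowsig.simulate import CompendiumConfig, gen_compendium

cfg = CompendiumConfig(n_datasets=30, informative_fraction=0.5, n_genes=1000,
                       loading=0.85, seed=1)
compendium, truth = gen_compendium(cfg)
module = set(truth.attrs["module_genes"])

result = screen(compendium, PRIMARY_QUERIES)
post = result.posteriors

print(f"datasets screened      : {len(compendium)} "
      f"({int(truth['informative'].sum())} informative by construction)")
print(f"genes selected (>0.5)  : {len(result.selected)}")
sens = (post[list(module)] > 0.5).mean()
fpr = (post[[g for g in post.index if g not in module]] > 0.5).mean()
print(f"module sensitivity     : {sens:.2f}")
print(f"background FPR         : {fpr:.4f}")
print("top genes by posterior :")
for g, p in post.sort_values(ascending=False).head(8).items():
    tag = "query" if g in set(PRIMARY_QUERIES.genes) else ("module" if g in module else "noise")
    print(f"  {g:<8} {p:.3f}  ({tag})")

# The posterior is the probability that a gene co-expresses with the query
# set given the evidence across all weighted datasets; the planted module
# should be recovered at high sensitivity with essentially no background.
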