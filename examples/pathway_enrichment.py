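"""Hypergeometric over-representation of a selected gene list.

Simulates data with a known active gene set, selects genes with CoxLasso,
and tests the selection against a small gene-set collection in which one
"pathway" deliberately contains the true actives.  The enriched pathway
should surface with a small adjusted p-value; random pathways should not.
N/K/n/k are universe size, pathway size in the universe, selection size and
overlap.
"""

import coxsislasso as cl

sim = cl.simulate_dataset(cl.strong_signal_config(
    n=250, p=200, n_active=5, censoring=0.25, seed=3))
ds = sim.dataset
support_ids = [ds.feature_ids[i] for i in sim.truth.support]
collection = cl.make_gene_sets(ds.feature_ids, support_ids,
                               n_sets=15, set_size=12, seed=3)

res = cl.run_coxlasso(ds, cl.StrategyConfig(
    n_folds=5, seed=0, n_lambda=50, lambda_min_ratio=0.05))
print(f"CoxLasso selected {len(res.selected_ids)} of {ds.p} genes\n")

enriched = cl.enrich(res.selected_ids, collection, universe=ds.feature_ids)
print(f"{'set':14s} {'N':>5} {'K':>4} {'n':>4} {'k':>3} "
      f"{'p':>10} {'p_adj':>10}")
for r in enriched[:6]:
    print(f"{r.set_name:14s} {r.N:5d} {r.K:4d} {r.n:4d} {r.k:3d} "
          f"{r.p_value:10.3g} {r.p_adjusted:10.3g}")
print("\noverlap of the top set:", enriched[0].overlap_ids)
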