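"""Convert a co-expression module into a motif-validated regulatory network.

A gradient-boosted regression per target ranks candidate TF -> target
edges by split gain; cis-regulatory motif enrichment (recovery AUC -> NES)
then discards edges without binding-site support.
"""

from scgrnet import grn, synthetic

# linear-regulation benchmark: 10 targets driven by one TF among 10
frame, driver, tfs, targets = synthetic.linear_regulation_fixture(seed=1)
edges = grn.infer_candidates(frame, tfs, targets, seed=1)
top = {}
for e in edges:
    if e.target not in top or e.importance > top[e.target].importance:
        top[e.target] = e
hits = sum(top[t].tf == driver for t in targets)
print(f"driver TF is the top-importance regulator for {hits}/{len(targets)} "
      "targets (boosted regression recovers the planted regulator)")

# motif filtering on the planted-regulon fixture
genes, truth, _, _ = synthetic.make_ground_truth()
db = synthetic.simulate_motif_db(truth, genes, signal_frac=0.9, seed=2)
tf_targets = {tf: sorted(r) for tf, r in truth.regulon.items()}
enr = grn.motif_enrichment(tf_targets, db)
for e in enr:
    if e.motif_id == f"motif_true_{e.tf}":
        print(f"{e.tf}: true motif AUC={e.auc:.3f}, NES={e.nes:.1f}, "
              f"enriched={e.enriched} "
              f"(NES >= 3 marks a binding motif supported regulon)")

cands = [grn.CandidateEdge(tf, t, 1.0)
         for tf, ts in tf_targets.items() for t in ts]
net = grn.prune_to_grn(cands, enr)
print(f"retained {len(net.edges)}/{len(cands)} candidate edges after the "
      "motif filter (each surviving edge carries its supporting motif)")
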