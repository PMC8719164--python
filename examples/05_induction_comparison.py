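"""Pre/post-induction comparison: fraction shifts and entropy decrease.

Simulates a paired experiment where the chondro-like subpopulation
expands from 67% to 91% under induction and its expression concentrates
onto the lineage program (driving entropy down), then runs the full
pipeline on both arms and tests the shifts.
"""

import mscheter as m

cfg = m.SimulationConfig(
    n_cells=1500, n_genes=1500,
    subpop_fractions=(0.67, 0.20, 0.13),
    induction_shift={"subpop0": 0.91, "subpop1": 0.013, "subpop2": 0.077},
    induction_concentration=2.0, seed=5)
pre, post = m.simulate_induction_pair(cfg)

programs = pre.uns["programs"]
sp_pre = m.process_sample(pre, programs=programs, seed=1)
sp_post = m.process_sample(post, programs=programs, seed=2)

res = m.fraction_shift_test(sp_pre.subpop_labels, sp_post.subpop_labels)
print(res[["fraction_pre", "fraction_post", "odds_ratio", "p_value", "stars"]]
      .round(4))
# The induced subpopulation's fraction rises from ~0.67 to ~0.91 and the
# Fisher test flags the shift (***); the shrinking subpopulations are
# flagged in the opposite direction.

e_pre = m.cell_entropy(sp_pre.counts)[sp_pre.subpop_labels == "subpop0"]
e_post = m.cell_entropy(sp_post.counts)[sp_post.subpop_labels == "subpop0"]
stat, p, direction = m.score_shift_test(e_pre, e_post)
print(f"induced-subpop entropy: pre {e_pre.mean():.4f} -> post "
      f"{e_post.mean():.4f} ({direction}, rank-sum p = {p:.2e})")
# Lower post-induction entropy mirrors the loss of stemness expected
# when cells commit to a lineage.
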