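"""Train the mutation policy and recover the hidden binding motifs.

Runs the reference study at reduced size (40 PPO iterations, 300 peptides
per allele) so it finishes in two to three minutes; the full study in
pepppo.workflows uses 80 iterations and 1000 peptides.
"""

from pepppo.workflows import motif_discovery_study, random_baseline_qualified_pct

study = motif_discovery_study(seed=7, iterations=40, n_generate=300)

print(study.metrics[["iteration", "mean_terminal_score", "qualified_fraction"]]
      .iloc[::5].round(3).to_string(index=False))
print()
for name in study.oracle.alleles:
    anchors = set(int(j) for j in study.oracle.anchors[(name, 9)])
    mark = lambda s: "".join(c if j in anchors else c.lower() for j, c in enumerate(s))
    print(
        f"{name}: qualified {study.qualified_pct[name]:5.1f}%   "
        f"recovered {mark(study.motifs[name].consensus())}   "
        f"hidden {mark(study.oracle.consensus(name, 9))}   "
        f"anchor similarity {study.anchor_similarity[name]:.3f}"
    )
print(f"random baseline qualified: {random_baseline_qualified_pct(study.oracle, 1000, 99):.2f}%")
print(
    "\nAnchor positions are upper-case; lower-case positions are near-uniform in the\n"
    "hidden motif, so their consensus letters are arbitrary.  Anchor similarity is\n"
    "1 minus the mean column Hellinger distance between the generated repertoire's\n"
    "PWM and the hidden PWM at the anchor columns; at this half-length demo run the\n"
    "anchors are already recovered while the qualified fraction is still climbing\n"
    "(the full 80-iteration study reaches 90%+)."
)
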