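"""Screen a synthetic mutation cohort with motif matching scores.

Expands point mutations into mutant 9-mer windows, scores each window
against per-allele PWMs (here the oracle's own hidden motifs, so no training
is needed), labels windows with the presentation oracle, and reports how
well the matching score separates neoantigens from non-neoantigens.
"""

from pepppo import PWM, evaluate_discrimination, make_hidden_oracle, screen, synth_cohort
from pepppo.screen import MutationRecord

oracle = make_hidden_oracle(n_alleles=3, lengths=(9,), seed=7)
cohort = synth_cohort(oracle, n_proteins=20, protein_length=120, n_mutations=60,
                      planted_fraction=0.3, seed=9)
records = [MutationRecord(r.protein_id, int(r.position), r.ref, r.alt, r.sample)
           for r in cohort.mutations.itertuples()]
pwms = {name: PWM(oracle.pwms[(name, 9)]) for name in oracle.alleles}

report, skipped = screen(records, cohort.proteins, pwms, cohort.alleles, oracle)
res = evaluate_discrimination(report.normalized_score, report.label)

print(f"{len(records)} mutations -> {len(report)} (peptide, allele) pairs, "
      f"{int(report.label.sum())} labeled neoantigens")
print(f"AUC {res['auc']:.3f}   rank-sum p {res['p_value']:.2e}")
print(f"median matching score: neoantigens {res['median_pos']:.3f} "
      f"vs non-neoantigens {res['median_neg']:.3f}")
print(
    "\nA third of the mutations were planted to create windows matching a hidden\n"
    "consensus; the motif matching score separates those cleanly from background\n"
    "mutations, which is the basis for rapid PWM-only neoantigen screening."
)
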