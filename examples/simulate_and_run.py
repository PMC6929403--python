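"""End-to-end run on a synthetic paired tumor/normal cohort.

Generates 20 patient pairs with 6 planted ceRNA triples plus decoy RNAs,
writes the TSV inputs, runs the whole pipeline (filter -> DE -> candidate
networks -> binarize -> PMI -> erfc selection -> assembly) and prints the
per-stage counts from the report.
"""

import tempfile
import warnings

from cernet import PipelineConfig, SyntheticConfig, run_pipeline, simulate_dataset, write_dataset

config = SyntheticConfig(
    n_pairs=20, n_planted=6, n_decoy_lnc=20, n_decoy_mr=20, n_decoy_mirna=4, seed=42
)
x, targets, truth = simulate_dataset(config)
print(f"simulated {x.n_rnas} RNAs x {x.n_samples} samples "
      f"({len(truth.triples)} planted triples, {targets.n_edges()} target edges)")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_dataset(x, targets, truth, tmp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny networks warn when dropped
        result = run_pipeline(
            PipelineConfig(
                expression_path=paths["expression"],
                metadata_path=paths["metadata"],
                targets_path=paths["targets"],
                out_dir=f"{tmp}/out",
            )
        )

report = result.report
print(f"RNAs retained after the expression filter: "
      f"{report.n_rnas_retained}/{report.n_rnas_input}")
print(f"differentially expressed (up/down): {report.de_counts}")
print(f"candidate networks: {report.n_candidate_networks}; "
      f"candidate crosstalks: {report.n_candidate_crosstalks}")
print(f"selected crosstalks (p < 0.05): {report.n_selected_crosstalks} "
      f"in {report.n_networks} ceRNA networks")
print()
print("Each candidate network is one miRNA with its sign-compatible DE")
print("targets; crosstalks are scored by PMI over binarized tumor samples")
print("and kept when erfc(theta/sqrt(2)) < 0.05 within the network.")
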