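"""Sweep sampling size and sampling time and summarize per arm.

The full study grid is 21 sampling sizes (40..80 step 2) x 60 sampling
times (N = 25..1500 step 25) = 1,260 cells; here a reduced grid keeps the
example quick.  Each cell fits one ensemble and reports all three arms from
the same fitted pools; the summary is the per-arm mean +/- SD over cells.
"""

import warnings

import votefuse as vf

warnings.filterwarnings("ignore")

sim = vf.simulate_cohort(vf.SimSpec(seed=1))
prep = vf.preprocess_cohorts(sim.train, sim.test)

grid = (40, 80, 20, 50, 150, 50)  # 3 sizes x 3 times = 9 cells
result = vf.run_sweep(
    sim.train, sim.test,
    prep.geno_train, prep.geno_test, prep.cyto_train, prep.cyto_test,
    grid=grid, classifier="lda", master_seed=1,
)
print(f"grid cells: {len(result.cells) // 3} (x 3 arms)")
print(result.summary.round(3).to_string())
print()
print("Rows are the three arms; columns are grid means and SDs.  A small SD")
print("at large sampling size / time indicates the ensemble has stabilized.")
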