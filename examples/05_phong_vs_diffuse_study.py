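"""A miniature paired Phong-vs-diffuse study through the pipeline.

Runs a single-plant arrangement over three lighting scenarios with both
optics models and both reflection settings, then prints the derived
summary: the indirect-light proportion, the absorbed-flux MAPE between
models and the green-band dominance of the local light field.  Ray count
is kept small here; increase n_rays for publication-quality error bars.
"""

from canopylight.pipeline import RunConfig, report, run_study

config = RunConfig(
    seed=1,
    n_rays=200_000,
    n_reps=2,
    arrangements=("single",),
    subset_q_direct=(0.5, 1.0),
    subset_altitude=(50.0,),
    include_pure_diffuse=True,
    out_dir="study_mini",
)
bundle = run_study(config)
bundle.write()
print(report(bundle))
print("\ntables written to", config.out_dir)
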