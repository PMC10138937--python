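"""The three-step metabolic pathway with gene regulation.

Six sentences — including the dense "Substrate S is converted into product P
through intermediates M1 and M2. The metabolic reactions are catalyzed by
three enzymes, E1, E2, and E3." — compile to 10 species and 15 reactions:
three Michaelis-Menten metabolic steps plus a four-reaction expression unit
(transcription, translation, mRNA decay, protein decay) per enzyme. Product
P represses the expression of E3 through a Hill factor on its transcription.
"""

from kintext import emit_antimony, get_problem, model_summary, simulate

problem = get_problem("three_step")
model = problem.build()
print(f"model size: {model_summary(model)[:2]} (species, reactions)")

mm_steps = [r for r in model.reactions
            if r.modifiers and r.reactants and not r.reactants[0].name.startswith("mRNA")]
print("metabolic steps:")
for r in mm_steps:
    print(f"  {r.id}: {r.reactants[0].name} -> {r.products[0].name}"
          f"  (enzyme {r.modifiers[0]})")

trajectory = simulate(model, t_end=problem.demo_t_end, n_points=201,
                      overrides=problem.demo_overrides)
mid = len(trajectory.times) // 2
for sid in ("S", "P", "E1", "E2", "E3"):
    s = trajectory.series(sid)
    print(f"{sid}: {s[0]:.2f} -> {s[mid]:.2f} (mid) -> {s[-1]:.2f}")
print("\nAntimony (first lines):")
print("\n".join(emit_antimony(model).splitlines()[:10]))
# While substrate lasts, E1 and E2 sit near their full expression level but
# E3 stays several-fold lower: accumulated P represses its transcription.
# S drains through M1 and M2 into P.
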