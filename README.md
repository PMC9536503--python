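# evolvex

Model-driven design of **adaptive laboratory evolution (ALE) environments**
from genome-scale (or toy) stoichiometric metabolic models.

Many industrially desirable metabolic traits — say, secretion of an aroma
compound in wine must — carry no fitness benefit in the environment where
they must manifest (the *application environment*), so they cannot be
selected for directly. `evolvex` searches for a different chemical
environment (the *evolution environment*) in which growth itself drags the
right fluxes along: a subset of the fluxes that must change for the trait
becomes *flux-coupled to growth*, forming a **tacking trait** that natural
selection can grip during serial-transfer evolution.

## Method

Given a stoichiometric matrix **S** with flux bounds, a growth reaction
(flux `v_mu`, the fitness proxy) and a desired trait flux `v_trait`:

1. **Flux basis** — the minimal set of fluxes that must leave the
   wild-type flux ranges `[w_lb,i, w_ub,i]` for the trait to reach a level
   `alpha · v_trait,max` in the application environment, found by the MILP

   ```
   min Σ yᵢ   s.t.  S·v = 0,  v_lb ≤ v ≤ v_ub,  v_trait ≥ α·v_trait,max,
                    yᵢ = 0 ⟹ w_lb,i ≤ vᵢ ≤ w_ub,i        (yᵢ ∈ {0,1})
   ```

   with `w_ub,i = w_max,i + δ|w_max,i| + ε` (and symmetrically below)
   relaxing the FVA ranges `[w_min,i, w_max,i]`. Alternative minimal bases
   are enumerated with integer cuts; each member is assigned an up or down
   direction by one-sided feasibility probes.

2. **Evolved state** — per candidate environment, the flux state that
   synthesizes an arbitrary unit of growth (`v_mu = 10`) from minimal
   total nutrient uptake, with every environment component consumed
   (`v_n ≤ −1`) and inhibited reactions zeroed.

3. **Response to selection** — the worst-case total growth coupling of the
   basis at the evolved state, `s_min = min Σ_u |v_u| − Σ_d |v_d|` (one
   MILP; absolute values linearized exactly with indicator binaries), plus
   per-member couplings by individual LPs. Members with nonzero coupling
   form the tacking trait.

4. **Coverage** — `b_min`, the worst-case number of basis members whose
   coupling is stronger than in a reference condition (factor `1 ± γ`),
   again as a MILP verified against brute force.

5. **Suitability score** (lower = better), combining selection strength,
   coverage and chemical parsimony (`z` = component count):

   ```
   score = 10³·(k − s_min)/(k + l) + 10³·(k + l − b_min)/(k + l) + z
   ```

All LPs/MILPs run on scipy's bundled HiGHS solver; no commercial solver is
needed. SBML Level 3 + FBC models are read through cobrapy (optional
`sbml` extra); a self-contained JSON dialect covers everything else.

## Worked example

The bundled toy network `TOY1` has two nutrients: on **A** the product P
can be bypassed entirely, on **B** every unit of growth co-produces one
unit of P. Designing an evolution environment for the trait `EX_P`
(P secretion) in application environment `{A}`:

```python
from evolvex import (Environment, EvolveXConfig, rank_environments)
from evolvex.fixtures import toy_network
from evolvex.model import NutrientCatalogue, CatalogueEntry

model = toy_network("TOY1")
app = Environment(frozenset({"EX_A"}), label="A")
cfg = EvolveXConfig(alpha=0.5, delta=0.0, epsilon=1e-6,
                    exclude_from_basis=frozenset({"GROWTH"}))
cat = NutrientCatalogue([CatalogueEntry("A", "EX_A", "carbon"),
                         CatalogueEntry("B", "EX_B", "carbon")])
for row in rank_environments(model, app, "EX_P", cat, app, cfg, max_size=1):
    print(row.environment.label, round(row.score, 2), sorted(row.tacking))
```

prints

```
B 1334.33 ['EX_P', 'R3']
A 5001.0 ['R3']
```

The flux basis of the trait is `{EX_P↑, R4↑, R3↓}` (k = 2, l = 1). On
**B** the trait flux is fully growth-coupled (coupling 10 at `v_mu` = 10),
giving `s_min = 0`, `b_min = 1` and score `10³·2/3 + 10³·2/3 + 1 =
1334.33`; on **A** the trait is uncoupled (`s_min = −10`, `b_min = 0`,
score 5001). The lower score correctly nominates **B** as the evolution
environment, although the trait itself confers no fitness advantage on
**A** — the tacking-trait logic in miniature.

The same pipeline is exposed on the command line:

```bash
evolvex rank --model toy1.json --app-env envA.yaml --trait EX_P \
        --catalogue nutrients.tsv --size 1 --out ranking.tsv
evolvex score --k 2 --l 1 --s-min 0 --b-min 1 --z 1   # -> 1334.333333
```

Growth-curve analysis (spline smoothing of log signal, maximum specific
growth rate, lag time) lives in `evolvex.growth`.

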