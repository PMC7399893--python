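# clts-cba

Ex-post cost–benefit analysis of a community-led total sanitation (CLTS)
intervention, built as a tested, reusable pipeline for health economists and
WASH (water, sanitation, hygiene) researchers who want to reproduce, probe,
or re-parameterize a trial-based societal CBA rather than a one-off
spreadsheet.

The model values a CLTS intervention in 24 rural Ethiopian villages over the
T = 10-year useful life of an improved latrine, in constant 2016
international dollars, against routine health-extension-worker activity:

    TB_PV = Σ_{t=1..T} Σ_k [ PDA_tk·VSL_t + DCA_tk·COI_tk + TS_tk·VOT_tk ] (1+r)^-t
    TC_PV = initial program + community costs + Σ_t (O&M_t + E_t)(1+r)^-t
    NPV   = TB_PV − TC_PV,   BCR = TB_PV / TC_PV

Averted child diarrhoea (1.566 days/child-year, scaled to older bands) is
valued three ways: averted deaths at a benefit-transferred value of a
statistical life, `VSL = 8.9 M × (1730/58700)^1.5`; averted cases at an
itemized cost of illness (treatment, transport, meals, accommodation, an
8-hour care day, health-worker time); and hours no longer spent walking to
open-defecation sites or borrowed latrines at a fraction of the mean wage.
Costs combine a top-down program ledger with a bottom-up community ledger
(people × hours × wage; latrine materials and construction time), with O&M
and hygiene education recurring at 10 % of annualized capital. One-way
(tornado) and 10,000-draw Monte Carlo sensitivity analyses sit on top, and a
synthetic cluster-trial generator with parameter-recovery estimators stands
in for the raw household data.

## Worked example

```python
import clts_cba as cba

p = cba.load_default_parameters()        # packaged base-case calibration
result = cba.run_scenario(p)
print(f"benefits {result.benefits.grand_total:,.0f}  "
      f"costs {result.costs.total_pv:,.0f}")
print(f"NPV {result.npv:,.0f}  BCR {result.bcr:.1f}  "
      f"per household {result.npv_per_household:,.0f}")

slip = cba.run_scenario(p, cba.Scenario(name="slippage"))  # 3.5 %/yr reversion
print(f"slippage: NPV {slip.npv:,.0f}  BCR {slip.bcr:.1f}")
```

prints

```
benefits 1,637,634  costs 444,928
NPV 1,192,707  BCR 3.7  per household 687
slippage: NPV 912,306  BCR 3.1
```

Benefits of ~$1.64 M (58 % from averted mortality) against costs of
~$0.44 M give a benefit–cost ratio of 3.7: each dollar invested returns
about $3.7 in health and time savings, or ~$687 of net benefit per
household. If latrine use decays 3.5 %/year the ratio falls to 3.1 — the
intervention stays clearly worthwhile.

The same pipeline is scriptable from the shell:

```sh
clts-cba run  --scenario slippage --out-dir out/
clts-cba oneway --out-dir out/                    # tornado CSV
clts-cba psa --seed 7 --n-draws 10000 --out-dir out/   # draws + CDF CSVs
clts-cba simulate --seed 1 --out-dir out/         # synthetic trial tables
clts-cba recover --seed 1 --n-replicates 50 --out-dir out/
```

`cba.one_way(p, cba.default_one_way_specs())` shows the result is most
sensitive to the trial effect (BCR 1.4–5.4 across its confidence interval)
and the latrine lifespan (1.9–5.4 across 5–15 years).

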