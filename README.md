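# pgpkinetics

Mass-action kinetic modelling of P-glycoprotein (P-gp) mediated drug efflux
and its inhibition by tyrosine kinase inhibitors (TKIs).

The package implements:

* **thermo** — thermodynamic parameter derivation: binding free energy ↔
  dissociation constant (1 M standard state, 310 K), membrane-partition
  corrected binding affinities (ΔG_mem = ΔG_aq + RT·ln PC), and
  transporter-copy-number → membrane-shell molarity conversions.
* **pgp_model** — the 16-variable mass-action ODE system: passive
  aqueous↔membrane drug exchange on both membrane faces, the nine-state
  (SBD × NBD) pump-binding lattice governed by four dissociation constants,
  and ATP-driven efflux. A 12-state noncompetitive variant (two independent
  SBD sub-sites) supports the calcein-assay fitting mode.
* **simulate** — scenario engine with a robust steady-state solver
  (chunked stiff integration + damped log-space Newton polish): TKI
  dose-response curves per pump level, mechanism knockouts (Kd → ∞),
  NBD/SBD transition-point detection on a log-ATP grid, and hypothetical
  10-fold parameter-improvement screens.
* **fitting** — grid-search estimation of a TKI's NBD dissociation constant
  from efflux-inhibition dose-response data (RMSE objective), under
  competitive or noncompetitive substrate-site assumptions.
* **synthetic_data** — seeded synthetic calcein-efflux inhibition datasets
  with known ground-truth Kd, plus the reference simulation scenario grid.
* **interface** (`config`/`cli`) — YAML run configuration, batch pipeline
  with artifact manifest, and the `pgpk` command-line tool.

## CLI

```bash
pgpk verify                      # reproduce the published reference values
pgpk derive --out params.csv     # derived membrane-phase Kds per compound
pgpk simulate dose-response --tki nilotinib --out dr.csv
pgpk simulate mechanisms --tki imatinib --out mech.csv
pgpk simulate transition-point --tki dasatinib --out tp.csv
pgpk simulate improve --tki dasatinib --fold 10 --out improve.csv
pgpk generate --tki nilotinib --true-kd 2e-9 --seed 1 --out ds.csv
pgpk fit --dataset ds.csv --tki nilotinib --binding noncompetitive --out fit.json
pgpk demo --out demo_dir         # small end-to-end run
```

All outputs are tidy CSV/JSON; simulations are deterministic (`--seed` is
accepted and recorded for provenance).

## Notes on reconstruction

Association rates are set to a common diffusion-limited 1e6 M⁻¹s⁻¹ with
k_off = Kd·k_on, so equilibria match the published dissociation constants;
absolute time scales are reconstructions. Passive exchange is first-order
per membrane face (reverse rate k_p/PC), giving the partition coefficient
as the equilibrium membrane/aqueous ratio. TKIs default to a faster
passive-exchange rate (10 s⁻¹) than paclitaxel (1 s⁻¹); with a common rate
the pump depletes the membrane TKI pool so strongly that no rate choice
reproduces the published inhibition regimes. Extracellular drug and
cytosolic ATP are clamped by default. Calcein assay surrogate constants
(reporter Kd 1 µM, PC 100, 2 µM effective pump) are reconstructions, chosen
to make the inhibition dose-response informative over the physiological
dose window.
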