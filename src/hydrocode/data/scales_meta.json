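{
  "logkwc_25": {
    "description": "log10 equilibrium constant for transfer of the amino-acid side chain from neutral aqueous solution to cyclohexane at 25 C (dimensionless).",
    "temperature_C": 25,
    "units": "log10 K",
    "provenance": "Transcribed from the published water-to-cyclohexane distribution coefficients of side-chain analogs (log10 Kw>c = dG(c->w)/1.364 at 25 C). Proline has no measured side-chain analog; its value (1.00) is an estimate placed in the mid-range of the neutral group.",
    "synthetic": false,
    "transcribed": "2026-09-19"
  },
  "logkwc_100": {
    "description": "SYNTHETIC STAND-IN for the 100 C log10 Kw>c scale (dimensionless).",
    "temperature_C": 100,
    "units": "log10 K",
    "provenance": "Constructed, not measured: v100 = v25 + 0.15*max(0, 1.7 - v25), rounded to 2 d.p. Emulates the reported qualitative temperature dependence (hydrophilic side chains become less hydrophilic with temperature; hydrophobic side chains are nearly unchanged). Use only where the true 100 C measurements are unavailable.",
    "synthetic": true,
    "transcribed": "2026-09-19"
  },
  "mean_buried_area": {
    "description": "Mean area buried on folding per residue, averaged over globular proteins.",
    "temperature_C": null,
    "units": "A^2",
    "provenance": "Transcribed from the published mean buried area table (Rose et al. 1985).",
    "synthetic": false,
    "transcribed": "2026-09-19"
  }
}
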