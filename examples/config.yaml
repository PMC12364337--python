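# Example run configuration: the five ALK inhibitors against the two
# effusion preferred terms, over the default 2013-2023 receipt window.
drugs:
  CRIZOTINIB: [XALKORI]
  CERITINIB: [ZYKADIA]
  ALECTINIB: [ALECENSA]
  BRIGATINIB: [ALUNBRIG]
  LORLATINIB: [LORBRENA, LORVIQUA]

events:
  Pleural effusion: [Pleural effusion]
  Pericardial effusion: [Pericardial effusion]

window:
  start: 2013-01-01
  end: 2023-12-31

criteria:
  min_ror: 2.00
  min_ci_low: 1.00
  min_reports: 10

require_primary_suspect: true

# Parameters for `pvsignal simulate`; omitted probabilities fall back to the
# generator's default vocabulary (five target drugs, common background drugs,
# effusion signals injected at the published odds-ratio regime).
synthetic:
  n_reports: 100000
  seed: 7
  duplicate_rate: 0.08
  secondary_role_rate: 0.15
  n_quarters: 4
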