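# Tissue-specific dose-response parameter registry.
#
# PTV caveat (read before trusting tcd50): published parameter tables for
# breast local control list the EUD volume-effect exponent a = -7.23 and the
# response slope gamma50 = 0.89, but a negative number cannot be a TCD50 (a
# dose), so the -7.23 entry is stored here as the EUD exponent and TCD50 must
# be supplied by configuration.  The 45 Gy default below is a placeholder in
# the clinically plausible range for 2-Gy-per-fraction breast control and is
# meant for relative (planned vs predicted) comparison, not absolute outcome
# prediction.
#
# Lung caveat: the pneumonitis row is stored as D50 = 26.16 Gy, gamma = 0.97,
# s = 0.012 (strongly parallel organ).  Source tables for this row are
# typographically ambiguous (a leading digit may or may not belong to D50);
# override via a user registry file if your institution uses different
# relative seriality lung parameters.
structures:
  PTV:
    endpoint: local_control
    model: tcp_eud
    eud_a: -7.23
    gamma50: 0.89
    tcd50: 45.0
  ipsilateral_lung:
    endpoint: pneumonitis
    model: relative_seriality
    d50: 26.16
    gamma: 0.97
    s: 0.012
  heart:
    endpoint: late_cardiac_mortality
    model: relative_seriality
    d50: 52.3
    gamma: 1.28
    s: 1.0
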