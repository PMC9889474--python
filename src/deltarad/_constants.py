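"""Shared physical constants."""

#: Average Gregorian month length; the single conversion point between the
#: inter-scan interval (days) and survival times (months).
DAYS_PER_MONTH = 30.44
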