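# Default health-factor vocabulary: maps structured EHR tobacco-status
# labels to follow-up smoking status.  The smoker and quitter lists contain
# the documented example labels plus common close variants; the smokeless
# list covers non-cigarette tobacco entries, which the outcome definition
# treats as cigarette-abstinent.  Sites may define local labels; anything
# not listed here is left unclassified and ignored by the linkage step.
match_mode: exact
smoker:
  - CURRENT SMOKER
  - CURRENTLY USES TOBACCO
  - TOBACCO CURRENT USER
  - CURRENT TOBACCO USER
  - TOBACCO USER
  - REFUSED SMOKING CESSATION
  - CURRENT EVERY DAY SMOKER
  - CURRENT SOME DAY SMOKER
quitter:
  - QUIT TOBACCO IN THE LAST 12 MONTHS
  - NON TOBACCO USER - QUIT IN PAST YEAR
  - CURRENT NON-TOBACCO USER
  - QUIT IN PAST YEAR
  - FORMER SMOKER - QUIT IN PAST YEAR
  - TOBACCO NON-USER
smokeless:
  - SMOKELESS TOBACCO USER
  - CURRENT SMOKELESS TOBACCO USER
  - CHEWING TOBACCO USER
  - USES SMOKELESS TOBACCO ONLY
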