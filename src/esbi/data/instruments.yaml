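schema_version: 1
# Questionnaire instruments as data: item texts, ordered response options,
# and the integer score attached to each option.  Editing wording here never
# touches scoring code; scoring reads the `scores` arrays.
instruments:
  AUDIT:
    name: Alcohol Use Disorders Identification Test
    items:
      - text: How often do you have a drink containing alcohol?
        options: [Never, Monthly or less, 2-4 times a month, 2-3 times a week, 4 or more times a week]
        scores: [0, 1, 2, 3, 4]
      - text: How many standard drinks do you have on a typical day when you are drinking?
        options: [1 or 2, 3 or 4, 5 or 6, 7 to 9, 10 or more]
        scores: [0, 1, 2, 3, 4]
      - text: How often do you have six or more standard drinks on one occasion?
        options: [Never, Less than monthly, Monthly, Weekly, Daily or almost daily]
        scores: [0, 1, 2, 3, 4]
      - text: How often during the last year have you found that you were not able to stop drinking once you had started?
        options: [Never, Less than monthly, Monthly, Weekly, Daily or almost daily]
        scores: [0, 1, 2, 3, 4]
      - text: How often during the last year have you failed to do what was normally expected of you because of drinking?
        options: [Never, Less than monthly, Monthly, Weekly, Daily or almost daily]
        scores: [0, 1, 2, 3, 4]
      - text: How often during the last year have you needed a first drink in the morning to get yourself going after a heavy drinking session?
        options: [Never, Less than monthly, Monthly, Weekly, Daily or almost daily]
        scores: [0, 1, 2, 3, 4]
      - text: How often during the last year have you had a feeling of guilt or remorse after drinking?
        options: [Never, Less than monthly, Monthly, Weekly, Daily or almost daily]
        scores: [0, 1, 2, 3, 4]
      - text: How often during the last year have you been unable to remember what happened the night before because of your drinking?
        options: [Never, Less than monthly, Monthly, Weekly, Daily or almost daily]
        scores: [0, 1, 2, 3, 4]
      - text: Have you or someone else been injured because of your drinking?
        options: [No, "Yes, but not in the last year", "Yes, during the last year"]
        scores: [0, 2, 4]
      - text: Has a relative, friend, doctor, or other health care worker been concerned about your drinking or suggested you cut down?
        options: [No, "Yes, but not in the last year", "Yes, during the last year"]
        scores: [0, 2, 4]
  LDQ:
    name: Leeds Dependence Questionnaire
    items:
      - text: Do you find yourself thinking about when you will next be able to have a drink?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Is drinking more important than anything else you might do during the day?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you feel your need for drink is too strong to resist?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you plan your days around getting and drinking alcohol?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you drink in a particular way in order to increase the effect it gives you?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you drink morning, afternoon and evening?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you feel you have to carry on drinking once you have started?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Is getting the effect you want more important than the particular drink you use?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you want to take more drink when the effect starts to wear off?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
      - text: Do you find it difficult to cope with life without drink?
        options: [Never, Sometimes, Often, Nearly always]
        scores: [0, 1, 2, 3]
  # PLACEHOLDER wording: the 5-item trauma-history screen is scored as a
  # count of affirmative answers; the item texts below are generic stand-ins
  # for the published scale, which is not reproduced in the program
  # description this engine implements.  Replace via a custom definitions
  # file for production use.
  TRAUMA:
    name: History of Trauma Scale (placeholder wording)
    placeholder: true
    items:
      - text: "Since your 18th birthday, have you had any fractures or dislocations of your bones or joints?"
        options: [No, Yes]
        scores: [0, 1]
      - text: "Since your 18th birthday, have you been injured in a road traffic accident?"
        options: [No, Yes]
        scores: [0, 1]
      - text: "Since your 18th birthday, have you injured your head?"
        options: [No, Yes]
        scores: [0, 1]
      - text: "Since your 18th birthday, have you been injured in an assault or fight?"
        options: [No, Yes]
        scores: [0, 1]
      - text: "Since your 18th birthday, have you been injured after drinking?"
        options: [No, Yes]
        scores: [0, 1]
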