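feature_code,description
A1,Apps provide information on consequences of exercise in general.
A2,Apps provide information on customized consequences of exercise.
A3,Apps provide information about others' approval of my exercise.
A4,Apps provide information about others' exercise status.
A5,Apps provide information about avoided movement in exercise.
A6,Apps help set exercise goals.
A7,Apps help set graded tasks by decomposing goals.
A8,Apps prompt review of exercise goals.
A9,Apps can check the extent to which previously set exercise goals were achieved.
A10,Apps remind me to record my exercise behavior.
A11,Apps can record my exercise behavior automatically.
A12,Apps can set the health goals to be achieved by exercise.
A13,Apps can prompt review of health goals.
A14,Apps can check the extent to which my expected goals were achieved.
A15,Apps remind me to keep records of my exercise outcome.
A16,Apps can automatically record my exercise outcome.
A17,Apps can assist me in detailed exercise planning.
A18,Apps can remind me to think about potential barriers in exercise planning.
A19,Apps can remind me to identify the ways of overcoming potential barriers when exercise planning.
A20,Apps prompt rewards contingent on effort toward exercise preparation.
A21,Apps provide rewards contingent on successful exercise.
A22,Apps provide graded use of contingent rewards over time.
A23,Apps prompt generalization of exercise.
A24,Apps remind me of past successful experience of exercise.
A25,Apps provide exercise records.
A26,Apps check the discrepancy between exercise performance and the set goals.
A27,Apps provide me with data about the discrepancy between my exercise performance and others'.
A28,Apps provide information on where and when to do the exercise.
A29,Apps provide instructions on how to do the exercise by text or voice.
A30,Apps show how to do the exercise through visual demonstrations.
A31,Apps can set context cues which remind me to exercise.
A32,Apps can set location cues which remind me to exercise.
A33,Apps can set people cues which remind me to exercise.
A34,Apps remind me to alter environment in ways so that it is more supportive of the exercise.
A35,Apps create the exercise goals as agreed behavioral contract.
A36,Apps prompt me to rehearse or repeat the exercise behavior numerous times.
A37,"Exercise reminders are gradually reduced in intensity, duration, and frequency over time."
A38,Apps facilitate social comparison.
A39,Apps make it easy to elicit social support to my exercise from other people.
A40,Apps remind me to focus on partners who are the exercise role models.
A41,Apps facilitate the discussion with exercise role models.
A42,Apps induce perceptions of future regret about not doing exercise.
A43,Apps provide risk information which evokes a fearful response.
A44,"Apps prompt self-talk to encourage, support, and maintain exercise."
A45,Apps prompt mental imagery (to imagine initiating or maintaining exercise is easy).
A46,Apps provide strategies in advance to avoid sustainability problem of exercise.
A47,Apps provide stress management to reduce anxiety to facilitate the performance of the exercise.
A48,Apps remind me to attend motivational interviewing which can minimize resistance and resolve ambivalence to change.
A49,Apps assist time management to make time for exercise.
A50,Apps provide general communication skills training.
A51,Apps stimulate anticipation of future rewards.
A52,Apps can set exercise time reminders.
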