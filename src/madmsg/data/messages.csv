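message_id,risk_content,theme,text,hashtag
H1,harms,alone,"Many people think smoking hookah is safer than cigarettes. Truth is, hookah tobacco has the same health effects—breathing problems, cancer, lung and heart disease.",#UnfollowHookah
H2,harms,alone,"The nicotine buzz comes with more than you bargained for. 'Hookah sickness' can be carbon monoxide poisoning.",#UnfollowHookah
HS1,harms,social,"Socializing at hookah bars isn't all fun and games. Smoking hookah with friends exposes you to even more poisonous chemicals than cigarette smoking.",#UnfollowHookah
HS2,harms,social,"Consider skipping your turn. Sharing a hookah hose increases your risk of infections like herpes.",#UnfollowHookah
HF1,harms,flavors,"",#UnfollowHookah
HF2,harms,flavors,"Don't let flavored hookah tobacco smooth talk you. Flavored hookah tobacco masks the nasty chemicals and is manufactured the same way as cigarettes.",#UnfollowHookah
A1,addiction,alone,"No one is invincible. Even smoking hookah just once or twice a month can lead to nicotine addiction.",#UnfollowHookah
A2,addiction,alone,"",#UnfollowHookah
AS1,addiction,social,"",#UnfollowHookah
AS2,addiction,social,"",#UnfollowHookah
AF1,addiction,flavors,"Mint, Blue Mist, Apple, Ambrosia. Flavors mask the bitter taste of nicotine and help get you hooked on smoking hookah.",#UnfollowHookah
AF2,addiction,flavors,"",#UnfollowHookah
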