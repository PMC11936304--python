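name,phase,category,unit_cost,quantity_rule,quantity,period_months
cell phone,startup,participant,149.99,per_participant_once,1,
phone case,startup,participant,12.99,per_participant_once,1,
arm band,startup,participant,8.99,per_participant_once,1,
charging block,startup,participant,3.50,per_participant_once,1,
USB-C charging cable,startup,participant,3.50,per_participant_once,1,
power bank,startup,participant,14.99,per_participant_once,1,
drawstring backpack,startup,participant,1.34,per_participant_once,1,
SMS platform implementation,startup,program,3588.00,per_program_once,1,
training materials printing,startup,program,618.59,per_program_once,1,
bus pass,recurring,participant,41.25,per_participant_per_month,1,
SIM card or phone plan,recurring,participant,210,per_participant_per_period,1,6
SMS platform maintenance,recurring,program,99,per_program_per_month,1,
HIE data access,recurring,program,200,per_program_per_hour,75,
program coordinator,recurring,personnel,17,per_program_per_hour,224,
case manager,recurring,personnel,32.44,per_program_per_hour,2500,
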